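"""De novo vs recurring germline variants across a mother-pup pedigree.

A pup's germline variant is *recurring* when it is also detected in any
maternal sample or in a sibling; otherwise it arose de novo in a single
oocyte.
"""

import pandas as pd

from mitolineage import SampleMeta, build_presence, classify_pedigree

TISSUES = ("brain", "heart", "kidney", "liver", "lung", "spleen", "skin")


def family_manifest():
    manifest = {}
    for animal, mother in (("mom", None), ("pup1", "mom"), ("pup2", "mom"),
                           ("pup3", "mom")):
        for t in TISSUES:
            m = SampleMeta(f"{animal}_{t}", animal, "polg_homozygous", 4.0,
                           "young", t, "bulk", mother_id=mother)
            manifest[m.sample_id] = m
    return manifest


manifest = family_manifest()
rows = [("mom_skin", 15104, "C", "T", 6.0)]               # mother's skin, 6%
rows += [(f"pup1_{t}", 15104, "C", "T", 13.0) for t in TISSUES]
rows += [(f"pup2_{t}", 6612, "C", "T", 20.0) for t in TISSUES]
rows += [("pup3_kidney", 6612, "C", "T", 5.0), ("pup3_lung", 6612, "C", "T", 6.0)]
rows += [(f"pup1_{t}", 4100, "G", "A", 9.0) for t in TISSUES]  # pup1-private
calls = pd.DataFrame(rows, columns=["sample_id", "pos", "ref", "alt",
                                    "heteroplasmy"])

mats = build_presence(calls, manifest)
pups = [mats[p] for p in ("pup1", "pup2", "pup3") if p in mats]
for key in [(15104, "C", "T"), (6612, "C", "T"), (4100, "G", "A")]:
    verdict = classify_pedigree(mats.get("mom"), pups, key)
    print(f"mt{key[0]} {key[1]}>{key[2]}: {verdict}")
# mt15104 is maternally transmitted (recurring); mt6612 is shared by two
# siblings though absent in the mother (recurring); mt4100 is private to one
# pup (de_novo).
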