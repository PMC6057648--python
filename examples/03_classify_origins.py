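"""Classify variant origins from sharing patterns across tissues and clones.

Three archetypal patterns for one animal with 7 bulk tissues and 3 skin
fibroblast clones: multi-organ sharing marks a germline (oocyte-inherited)
variant, single-organ confinement an early-embryonic one, and a single-clone
private variant a late somatic mutation.
"""

import pandas as pd

from mitolineage import SampleMeta, build_presence, classify_all

TISSUES = ("brain", "heart", "kidney", "liver", "lung", "spleen", "skin")
manifest = {}
for t in TISSUES:
    m = SampleMeta(f"m1_{t}", "m1", "wt", 20.0, "old", t, "bulk")
    manifest[m.sample_id] = m
for c in (1, 2, 3):
    m = SampleMeta(f"m1_sf{c}", "m1", "wt", 20.0, "old", "skin", "sf_clone",
                   clone_id=f"sf{c}")
    manifest[m.sample_id] = m

rows = []
for t in ("brain", "heart", "kidney", "liver"):      # germline pattern
    rows.append((f"m1_{t}", 3366, "G", "A", 25.0))
for s in ("m1_skin", "m1_sf1", "m1_sf2", "m1_sf3"):  # embryonic pattern
    rows.append((s, 2080, "G", "A", 90.0))
rows.append(("m1_sf2", 9056, "C", "T", 40.0))        # somatic pattern
calls = pd.DataFrame(rows, columns=["sample_id", "pos", "ref", "alt",
                                    "heteroplasmy"])

matrix = build_presence(calls, manifest)["m1"]
for o in classify_all(matrix):
    print(f"mt{o.key[0]} {o.key[1]}>{o.key[2]}: {o.origin}"
          f" (organs={o.n_organs}, clones={o.n_clones},"
          f" mean het={matrix.mean_heteroplasmy(o.key):.1f}%)")
# mt3366 spans 4 organs -> germline; mt2080 is confined to the skin lineage
# (bulk + all clones) -> early_embryonic; mt9056 is private to one clone ->
# somatic.
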