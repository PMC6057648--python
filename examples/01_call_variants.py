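"""Call heteroplasmic variants from a small allele-count table.

Builds three sites for one sample and runs the threshold caller: a variant is
reported when its mutant allele fraction is >= 2% of the site's total base
coverage and the site has >= 1000x coverage.
"""

from mitolineage import SiteAlleleCounts, call_sample, mouse_scaffold

genome = mouse_scaffold()

def site(pos, alt_fwd, alt_rev, ref_fwd=2300, ref_rev=2250):
    ref = genome.base_at(pos)
    alt = "A" if ref != "A" else "G"
    counts = {b: (0, 0) for b in "ACGT"}
    counts[ref] = (ref_fwd, ref_rev)
    counts[alt] = (alt_fwd, alt_rev)
    return SiteAlleleCounts("skin_bulk", pos, ref, counts)

sites = [
    site(3366, 60, 55),                       # ~2.5% -> called
    site(9056, 20, 18),                       # ~0.8% -> below threshold
    site(13029, 150, 140, 300, 290),          # 33% but coverage 880 -> too shallow
]

calls = call_sample(sites, genome)
print(f"{len(calls)} passing call(s) out of {len(sites)} sites:")
for c in calls:
    print(f"  mt{c.position} {c.ref}>{c.alt}  heteroplasmy {c.heteroplasmy:.2f}%"
          f"  coverage {c.coverage}")
# The 2.47% call passes both filters; the 0.83% allele is below the 2%
# detection threshold and the deep-variant site fails the 1000x coverage rule.
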