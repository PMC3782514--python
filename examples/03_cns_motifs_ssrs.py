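#!/usr/bin/env python
"""Conserved non-coding sequences, cis-regulatory motifs, and SSRs.

We simulate three homologous regions ("A", "B", "D") sharing three implanted
conserved non-coding segments (CNS) at ~88% identity, then ask the detector
to find them blind. A CNS must be >= 100 bp at >= 80% identity in every
pairwise comparison, lie between the same pair of anchor genes in all
regions, and not overlap annotated genic sequence. Detected coordinates are
compared against the generator's truth. We then scan one region for
cis-regulatory elements (exact IUPAC consensus matches on both strands) and
simple sequence repeats (maximal perfect tandem repeats of 1-6 bp units).

Run: python examples/03_cns_motifs_ssrs.py
"""

from syntevol.cns import CNSParams, find_cns, find_ssrs, scan_cis_elements
from syntevol.simulate import SimConfig, simulate_trio_with_cns

regions, truth = simulate_trio_with_cns(SimConfig(seed=42), n_cns=3, cns_identity=0.88)
print(f"regions: {', '.join(f'{r.id} ({len(r.residues)} bp)' for r in regions)}")

records = find_cns(regions, CNSParams())
print(f"\ndetected CNS: {len(records)} (3 implanted)")
for rec, (ts, te) in zip(records, truth.cns["A"]):
    s, e = rec.intervals["A"]
    print(
        f"  {rec.label}: {rec.length} bp, min pairwise identity "
        f"{rec.min_identity:.3f}, A[{s}:{e}) vs truth A[{ts}:{te})"
    )

region_a = regions[0]
hits = scan_cis_elements(region_a.residues)
print(f"\ncis-element hits in region A: {len(hits)}")
by_name: dict[str, int] = {}
for h in hits:
    by_name[h.name] = by_name.get(h.name, 0) + 1
for name, n in sorted(by_name.items()):
    print(f"  {name}: {n}")

# The trio generator implants only CNS; the full-region generator also
# implants SSR tracts, so scan one of its lineages instead.
from syntevol.simulate import simulate_lineages

(full_a, _), full_truth = simulate_lineages(SimConfig(seed=42), ("A", "B"))
ssrs = find_ssrs(full_a.residues)
print(f"\nSSR tracts in simulated full region A: {len(ssrs)}")
for ssr in ssrs[:5]:
    print(f"  ({ssr.unit}){ssr.copies} at [{ssr.start}:{ssr.end})")
if len(ssrs) > 5:
    print(f"  ... and {len(ssrs) - 5} more")
print(f"implanted SSR tracts (truth): {len(full_truth.ssrs['A'])}")
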