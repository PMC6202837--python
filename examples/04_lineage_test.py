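"""Derived-allele-sharing lineage assignment on simulated reads.

Constructs Neandertal- and Denisovan-diagnostic sites, simulates a sample
sharing 40% of Neandertal-derived and 10% of Denisovan-derived alleles, and
runs the sharing percentages with 90% binomial intervals plus the Fisher
exact comparison.
"""

import numpy as np

from spuriometer import InformativeSite, Lineage, derived_sharing, lineage_test
from spuriometer.io import ReadAlignment

rng = np.random.default_rng(5)
sites, alns = [], []
for i in range(400):
    pos = 30 + 40 * i
    lineage = Lineage.NEANDERTAL if i % 2 == 0 else Lineage.DENISOVAN
    sites.append(InformativeSite("chr1", pos, "A", "G", lineage))
    q = 0.40 if lineage is Lineage.NEANDERTAL else 0.10
    base = "G" if rng.random() < q else "A"
    alns.append(
        ReadAlignment(
            qname=f"r{i}", ref_name="chr1", ref_start=pos - 12,
            seq="A" * 12 + base + "A" * 12, cigar="25M", is_reverse=False,
        )
    )

sharing = derived_sharing(alns, sites, min_len=20)
for lineage in (Lineage.NEANDERTAL, Lineage.DENISOVAN):
    cs = sharing.classes[lineage]
    lo, hi = cs.ci(alpha=0.10)
    print(f"{lineage.value:12s} shared {cs.k:3d}/{cs.n:3d} = {cs.pct:5.1f}%  "
          f"(90% CI {lo:.1f}-{hi:.1f}%)")
print(f"Neandertal vs Denisovan Fisher exact p = {lineage_test(sharing):.3g}")
# Substantially higher Neandertal sharing with a small p assigns the sample
# to the Neandertal lineage; overlapping intervals would leave it unresolved.
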