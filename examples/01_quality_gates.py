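"""Validate an ortholog cluster: frame checks, cluster size, alignment quality.

Builds a small synthetic cluster, then runs the three gates applied before
any selection analysis: the minimum-cluster-size gate (orthologs from at
least six species besides the focal gene), the alignment-quality gate
(column-averaged normalised similarity, threshold 0.6, with drop-worst-and-
retry), and per-column gap fractions (columns with more than 40% gaps later
mask candidate sites).
"""

import numpy as np

import imprintsel as ims

tree = ims.PhyloTree.from_newick(
    "((AT1G00001:0.3,sp1:0.2):0.1,(sp2:0.25,sp3:0.1):0.12,"
    "(sp4:0.3,sp5:0.2):0.08,sp6:0.35);"
)
params = ims.CodonModelParams(kappa=2.0, site_classes=[ims.SiteClass(0.3, 1.0)])
alignment, _ = ims.simulate_codon_alignment(tree, params, n_sites=120, seed=4)
cluster = ims.OrthologCluster("AT1G00001", alignment, tree)

gate = ims.cluster_size_gate(cluster, min_species=6)
print(f"cluster-size gate: {'pass' if gate.passed else 'fail'} ({gate.reason})")

quality = ims.quality_gate(alignment, threshold=0.6, drop_and_retry=True)
print(f"quality gate:      {'pass' if quality.passed else 'fail'} "
      f"(score {quality.score:.3f}, removed {quality.removed or 'none'})")

gaps = ims.column_gap_fraction(alignment)
print(f"gap fractions:     max {gaps.max():.2f} over {len(gaps)} codon columns; "
      f"{int((gaps > 0.40).sum())} column(s) would mask candidate sites")

# The score is 1.0 for identical sequences and decreases as columns disagree;
# a cluster passing all three gates proceeds to the model fits.
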