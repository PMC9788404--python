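"""Bootstrap cluster support on planted two-subtype data.

Builds a 20-patient cohort with two planted subtypes (luminal-like and
basal-like marker profiles), clusters patients on correlation distance with
average linkage, and runs the multiscale bootstrap (nboot = 1000) to attach
AU/BP support to every node.
"""

from ihcsubtype import (
    attach_support,
    average_linkage_tree,
    correlation_distance,
    label_cluster,
    significant_clusters,
)
from ihcsubtype.synthetic import planted_block_matrix

matrix, membership = planted_block_matrix({"luminal": 10, "basal": 10}, seed=1)
tree = average_linkage_tree(correlation_distance(matrix), matrix.patient_ids)
attach_support(tree, matrix, nboot=1000, seed=1)

clusters, unassigned = significant_clusters(tree, alpha=0.95)
print(f"Significant clusters at AU >= 0.95: {len(clusters)}")
for node in clusters:
    label = label_cluster(tree.member_labels(node), matrix, cutoff=20)
    print(
        f"  {label.major:8s} ({label.sub})  n={len(node.members):2d}  "
        f"AU={tree.support.loc[node.id, 'au']:.3f}  "
        f"BP={tree.support.loc[node.id, 'bp']:.3f}"
    )
print(f"Unassigned patients: {unassigned or 'none'}")
print(
    "\nAU is the multiscale-bootstrap (approximately unbiased) support;"
    " both planted subtypes are recovered with near-certain support."
)
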