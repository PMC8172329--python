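"""FEGS: alignment-free protein feature extraction and phylogeny.

A protein sequence is encoded as a fused numerical vector: one
length-normalized leading eigenvalue of the L/L matrix of a cone-based 3D
graphical curve per physicochemical property (158 in the canonical
configuration), plus amino-acid composition (20) and dipeptide
composition (400) — 578 dimensions in total.  Downstream, PCA-reduced
vectors are compared by cosine distance and clustered hierarchically into
trees evaluated with the adjusted Rand index.
"""

from importlib import resources

from .aaindex import (
    STANDARD_AMINO_ACIDS,
    PropertyIndex,
    PropertySet,
    amino_acid_order,
    deduplicate,
    load_property_set,
    parse_aaindex,
)
from .composition import aac, dpc
from .features import (
    FEGSVectorizer,
    feature_matrix,
    fegs_vector,
    n_components_for_variance,
    pca_reduce,
)
from .graphical import (
    ConeEmbedding,
    build_cone,
    build_path,
    graphical_features,
    leading_eigenvalue,
    ll_matrix,
)
from .io import SequenceRecord, read_fasta, read_labels, write_fasta, write_labels
from .phylogeny import (
    HierarchicalPhylogeny,
    adjusted_rand_index,
    cosine_distance_matrix,
    cut_tree,
    linkage_tree,
    to_newick,
)
from .simulate import (
    generate_protein_families,
    generate_random_proteins,
    synthetic_property_set,
)

__version__ = "0.1.0"

__all__ = [
    "STANDARD_AMINO_ACIDS",
    "PropertyIndex",
    "PropertySet",
    "parse_aaindex",
    "deduplicate",
    "amino_acid_order",
    "load_property_set",
    "ConeEmbedding",
    "build_cone",
    "build_path",
    "ll_matrix",
    "leading_eigenvalue",
    "graphical_features",
    "aac",
    "dpc",
    "FEGSVectorizer",
    "fegs_vector",
    "feature_matrix",
    "pca_reduce",
    "n_components_for_variance",
    "HierarchicalPhylogeny",
    "cosine_distance_matrix",
    "linkage_tree",
    "cut_tree",
    "to_newick",
    "adjusted_rand_index",
    "SequenceRecord",
    "read_fasta",
    "write_fasta",
    "read_labels",
    "write_labels",
    "generate_random_proteins",
    "generate_protein_families",
    "synthetic_property_set",
    "bundled_fixture_properties",
]


def bundled_fixture_properties() -> PropertySet:
    """The small synthetic AAindex-format fixture shipped with the package
    (5 usable indices after NA-filtering and deduplication)."""
    text = (
        resources.files("fegs").joinpath("data/synthetic_aaindex.txt").read_text()
    )
    indices, _ = parse_aaindex(text)
    return deduplicate(indices, source="bundled")
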