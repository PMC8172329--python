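"""Cone-based 3D graphical curves and their spectral descriptors.

For one physicochemical property, the 20 amino acids are sorted ascending
by property value and placed on the unit circle of a right circular cone's
base plane at height z = 1::

    phi(Omega_i) = (cos(2*pi*i/20), sin(2*pi*i/20), 1),   i = 1..20

Each of the 400 ordered amino-acid pairs sits a quarter of the way along
the chord from the first vertex to the second::

    phi(Omega_i Omega_j) = phi(Omega_i) + (phi(Omega_j) - phi(Omega_i)) / 4

A protein sequence s_1..s_N walks a 3D path from the origin: the step for
residue i adds the residue's vertex plus the frequency-weighted sum of all
pair points over the dipeptides seen in the prefix s_1..s_i.  The path's
L/L matrix divides every pairwise Euclidean (line) distance by the arc
length along the curve between the same two points; its largest
eigenvalue, normalized by sequence length, is the one-number descriptor of
the curve.  One descriptor per property gives the graphical feature block.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.sparse.linalg import eigsh
from scipy.spatial.distance import pdist, squareform

from .aaindex import STANDARD_AMINO_ACIDS, PropertySet, amino_acid_order

# above this size a dense full-spectrum solve is replaced by Lanczos
_DENSE_EIG_LIMIT = 2000

_AA_TO_COL = {aa: i for i, aa in enumerate(STANDARD_AMINO_ACIDS)}


@dataclass(frozen=True)
class ConeEmbedding:
    """Vertex and pair-point coordinates for one amino-acid ordering.

    ``vertices[k]`` is the 3D point of ``order[k]`` (cone index i = k + 1);
    ``pair_points[a, b]`` is the point of the ordered pair (aa_a, aa_b),
    indexed by canonical alphabetical amino-acid position, not cone index.
    """

    order: tuple[str, ...]
    vertices: np.ndarray  # (20, 3), row k = phi(order[k])
    pair_points: np.ndarray  # (20, 20, 3) in canonical A..Y indexing

    def vertex(self, aa: str) -> np.ndarray:
        return self.vertices[self.order.index(aa)]

    def pair_point(self, a: str, b: str) -> np.ndarray:
        return self.pair_points[_AA_TO_COL[a], _AA_TO_COL[b]]


def build_cone(order: list[str] | tuple[str, ...]) -> ConeEmbedding:
    """Place the 20 amino acids (in the given ascending order) on the cone.

    The k-th element of ``order`` (1-based) receives cone index i = k, so
    the last-sorted amino acid lands at angle 2*pi, i.e. the point (1, 0, 1).
    """
    order = tuple(order)
    if sorted(order) != sorted(STANDARD_AMINO_ACIDS):
        raise ValueError(
            "order must be a permutation of the 20 standard amino acids, "
            f"got {order!r}"
        )
    i = np.arange(1, 21)
    theta = 2.0 * np.pi * i / 20.0
    vertices = np.column_stack([np.cos(theta), np.sin(theta), np.ones(20)])

    # re-index vertices into canonical A..Y order for pair-point arithmetic
    canon = np.empty((20, 3))
    for k, aa in enumerate(order):
        canon[_AA_TO_COL[aa]] = vertices[k]
    pair_points = canon[:, None, :] + 0.25 * (canon[None, :, :] - canon[:, None, :])
    return ConeEmbedding(order=order, vertices=vertices, pair_points=pair_points)


def build_path(
    sequence: str,
    cone: ConeEmbedding,
    freq_mode: str = "count",
) -> np.ndarray:
    """Extend the 3D protein path for ``sequence`` on ``cone``.

    Returns the (N, 3) array of points P_1..P_N; the origin P_0 = (0,0,0)
    is implicit.  ``freq_mode`` selects the dipeptide frequency convention
    in the step equation: ``"count"`` uses raw occurrence counts within the
    prefix (so z_i = i(i+1)/2 exactly), ``"relative"`` divides the counts
    by the i-1 overlapping windows of the prefix.
    """
    if freq_mode not in ("count", "relative"):
        raise ValueError(f"freq_mode must be 'count' or 'relative', got {freq_mode!r}")
    n = len(sequence)
    if n == 0:
        raise ValueError("sequence must be nonempty")
    try:
        cols = np.array([_AA_TO_COL[aa] for aa in sequence])
    except KeyError as exc:
        raise ValueError(f"non-standard residue {exc.args[0]!r} in sequence") from None

    canon = np.empty((20, 3))
    for k, aa in enumerate(cone.order):
        canon[_AA_TO_COL[aa]] = cone.vertices[k]

    points = np.empty((n, 3))
    pos = np.zeros(3)
    # running sum of count-weighted pair points over the prefix; in count
    # mode each step i >= 2 adds exactly one new dipeptide occurrence
    pair_sum = np.zeros(3)
    for i in range(n):
        if i >= 1:
            pair_sum = pair_sum + cone.pair_points[cols[i - 1], cols[i]]
        if freq_mode == "count" or i == 0:
            freq_term = pair_sum if i >= 1 else np.zeros(3)
        else:
            freq_term = pair_sum / i  # i = (prefix length) - 1 windows
        pos = pos + canon[cols[i]] + freq_term
        points[i] = pos
    return points


def ll_matrix(path: np.ndarray) -> np.ndarray:
    """The L/L (line/length) matrix of a 3D path P_1..P_N.

    Entry (i, j) is the Euclidean distance between P_i and P_j divided by
    the summed lengths of the path edges between them; the diagonal is
    zero.  Requires N >= 2.
    """
    path = np.asarray(path, dtype=float)
    n = path.shape[0]
    if path.ndim != 2 or path.shape[1] != 3:
        raise ValueError(f"path must be an (N, 3) array, got shape {path.shape}")
    if n < 2:
        raise ValueError("L/L matrix requires a path of at least 2 points")
    chord = squareform(pdist(path))
    edge = np.linalg.norm(np.diff(path, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(edge)])
    arc = np.abs(cum[:, None] - cum[None, :])
    with np.errstate(invalid="ignore", divide="ignore"):
        m = np.where(arc > 0, chord / np.where(arc > 0, arc, 1.0), 0.0)
    np.fill_diagonal(m, 0.0)
    return m


def leading_eigenvalue(m: np.ndarray) -> float:
    """Largest eigenvalue of a symmetric matrix.

    Dense full-spectrum solve up to 2000x2000, Lanczos (``eigsh``) above;
    for the nonnegative symmetric L/L matrix this equals the spectral
    radius.
    """
    m = np.asarray(m, dtype=float)
    n = m.shape[0]
    if m.ndim != 2 or m.shape[1] != n:
        raise ValueError(f"expected a square matrix, got shape {m.shape}")
    if n <= _DENSE_EIG_LIMIT:
        return float(np.linalg.eigvalsh(m)[-1])
    return float(eigsh(m, k=1, which="LA", return_eigenvectors=False)[0])


def graphical_features(
    sequence: str,
    properties: PropertySet,
    freq_mode: str = "count",
) -> np.ndarray:
    """Length-normalized leading eigenvalues, one per property index.

    Component p is ``leading_eigenvalue(ll_matrix(path_p)) / N`` where
    path_p is the curve built on the cone of property p.  Distinct
    properties that induce the same amino-acid ordering share a curve, so
    cones and descriptors are cached per ordering.
    """
    n = len(sequence)
    if n < 2:
        raise ValueError("graphical features require a sequence of length >= 2")
    out = np.empty(len(properties))
    cache: dict[tuple[str, ...], float] = {}
    for p, idx in enumerate(properties):
        order = tuple(amino_acid_order(idx))
        if order not in cache:
            cone = build_cone(order)
            path = build_path(sequence, cone, freq_mode=freq_mode)
            cache[order] = leading_eigenvalue(ll_matrix(path)) / n
        out[p] = cache[order]
    return out


def export_path_xyz(path: np.ndarray) -> str:
    """Serialize a path as 3-column whitespace-separated XYZ text."""
    return "".join(f"{x:.12g} {y:.12g} {z:.12g}\n" for x, y, z in np.asarray(path))
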