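"""Grantham physicochemical distance and per-site sequence divergence.

The Grantham distance between two amino acids combines squared differences
in side-chain composition (c), polarity (p) and volume (v):

    d(i, j) = scale * [alpha*(c_i - c_j)^2 + beta*(p_i - p_j)^2
                       + gamma*(v_i - v_j)^2]^(1/2)

With the canonical constants (alpha=1.833, beta=0.1018, gamma=0.000399,
scale=50.723) the mean over the 190 distinct residue pairs is 100, which is
the calibration of the published integer matrix.  The per-site divergence of
two aligned protein sequences (the HED building block) is the mean Grantham
distance over positions where both sequences carry a standard residue; gap
('-') and unknown ('X') columns are skipped and excluded from the
denominator.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass

import numpy as np

STANDARD_RESIDUES = "ARNDCQEGHILKMFPSTWYV"
GAP_CHARS = frozenset("-X")

#: Canonical weights of the distance formula and the normalising constant
#: that calibrates the mean distinct-pair distance to 100.
CANONICAL_ALPHA = 1.833
CANONICAL_BETA = 0.1018
CANONICAL_GAMMA = 0.000399
CANONICAL_SCALE = 50.723


class GranthamError(ValueError):
    """Raised for invalid residues, ragged alignments or bad configuration."""


@dataclass(frozen=True)
class ResidueProperties:
    """Side-chain properties of one residue (Grantham's c, p, v)."""

    residue: str
    composition: float
    polarity: float
    volume: float

    def __post_init__(self) -> None:
        if len(self.residue) != 1 or self.residue not in STANDARD_RESIDUES:
            raise GranthamError(f"non-standard residue {self.residue!r}")
        for field in ("composition", "polarity", "volume"):
            v = getattr(self, field)
            if not np.isfinite(v) or v < 0:
                raise GranthamError(
                    f"{field} of residue {self.residue!r} must be finite and "
                    f"non-negative, got {v!r}"
                )


@dataclass(frozen=True)
class DistanceParams:
    """Weights and scale of the Grantham distance formula."""

    alpha: float = CANONICAL_ALPHA
    beta: float = CANONICAL_BETA
    gamma: float = CANONICAL_GAMMA
    scale: float = CANONICAL_SCALE

    def __post_init__(self) -> None:
        for field in ("alpha", "beta", "gamma", "scale"):
            v = getattr(self, field)
            if not (np.isfinite(v) and v > 0):
                raise GranthamError(f"{field} must be strictly positive, got {v!r}")


def load_residue_properties() -> dict[str, ResidueProperties]:
    """Load the embedded residue property table (20 standard residues)."""
    text = (
        importlib.resources.files("hedratio.data")
        .joinpath("grantham_properties.tsv")
        .read_text()
    )
    props: dict[str, ResidueProperties] = {}
    for line in text.splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        residue, c, p, v = line.split("\t")
        if residue in props:
            raise GranthamError(f"duplicate residue {residue!r} in property table")
        props[residue] = ResidueProperties(residue, float(c), float(p), float(v))
    missing = set(STANDARD_RESIDUES) - set(props)
    if missing:
        raise GranthamError(f"property table missing residues: {sorted(missing)}")
    return props


class GranthamMatrix:
    """Symmetric 20x20 residue-pair distance matrix with zero diagonal.

    Entries are kept unrounded; the published table is the integer rounding
    of these values (its own rounding differs by at most 1 on a few pairs).
    """

    def __init__(self, residues: str, values: np.ndarray):
        self.residues = residues
        self._index = {r: i for i, r in enumerate(residues)}
        self.values = values

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        try:
            return float(self.values[self._index[a], self._index[b]])
        except KeyError as exc:
            raise GranthamError(f"non-standard residue {exc.args[0]!r}") from None

    @property
    def max_distance(self) -> float:
        return float(self.values.max())

    def mean_pair_distance(self) -> float:
        """Mean over the 190 unordered distinct residue pairs."""
        iu = np.triu_indices(len(self.residues), k=1)
        return float(self.values[iu].mean())


def build_grantham_matrix(
    props: dict[str, ResidueProperties] | None = None,
    params: DistanceParams | None = None,
) -> GranthamMatrix:
    """Build the full symmetric Grantham matrix from residue properties.

    Raises :class:`GranthamError` if any of the 20 standard residues is
    missing from ``props``.
    """
    if props is None:
        props = load_residue_properties()
    if params is None:
        params = DistanceParams()
    missing = set(STANDARD_RESIDUES) - set(props)
    if missing:
        raise GranthamError(f"missing residue properties: {sorted(missing)}")
    c = np.array([props[r].composition for r in STANDARD_RESIDUES])
    p = np.array([props[r].polarity for r in STANDARD_RESIDUES])
    v = np.array([props[r].volume for r in STANDARD_RESIDUES])
    sq = (
        params.alpha * np.subtract.outer(c, c) ** 2
        + params.beta * np.subtract.outer(p, p) ** 2
        + params.gamma * np.subtract.outer(v, v) ** 2
    )
    return GranthamMatrix(STANDARD_RESIDUES, params.scale * np.sqrt(sq))


def residue_distance(a: str, b: str, matrix: GranthamMatrix) -> float:
    """Distance between two standard residues; 0 iff ``a == b``."""
    return matrix[a, b]


def pairwise_sequence_hed(seq_a: str, seq_b: str, matrix: GranthamMatrix) -> float:
    """Per-site mean Grantham distance between two aligned sequences.

    A position contributes iff both characters are standard residues;
    positions with '-' or 'X' in either sequence are skipped and do not
    count toward the denominator.  Symmetric in its arguments.

    Raises :class:`GranthamError` on length mismatch, on characters outside
    {standard residues, '-', 'X'}, and when no position is comparable (the
    divergence is then undefined).
    """
    if len(seq_a) != len(seq_b):
        raise GranthamError(
            f"aligned sequences differ in length: {len(seq_a)} vs {len(seq_b)}"
        )
    total = 0.0
    n = 0
    for x, y in zip(seq_a, seq_b):
        x_gap, y_gap = x in GAP_CHARS, y in GAP_CHARS
        if not x_gap and x not in matrix._index:
            raise GranthamError(f"non-standard residue {x!r}")
        if not y_gap and y not in matrix._index:
            raise GranthamError(f"non-standard residue {y!r}")
        if x_gap or y_gap:
            continue
        total += matrix[x, y]
        n += 1
    if n == 0:
        raise GranthamError("no comparable positions; divergence undefined")
    return total / n


def pool_hed_matrix(sequences: list[str], matrix: GranthamMatrix) -> np.ndarray:
    """Pairwise per-site HED between every pair in a list of aligned sequences.

    Convenience used by the simulator and profile scoring to avoid
    recomputing per-subject: entry [i, j] is pairwise_sequence_hed of
    sequences i and j (0 on the diagonal).
    """
    k = len(sequences)
    out = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            out[i, j] = out[j, i] = pairwise_sequence_hed(
                sequences[i], sequences[j], matrix
            )
    return out
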