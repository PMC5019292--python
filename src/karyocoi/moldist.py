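"""Pairwise nucleotide distances for barcode alignments.

Implements the p-distance, Kimura two-parameter (K2P) distance, the
Tamura–Nei (TN93) distance and the gamma-rate-heterogeneity-corrected K2P,
plus alignment-level pairwise matrices and between-species mean distances —
the standard summaries of DNA-barcoding studies.

For two aligned sequences let P be the proportion of sites differing by a
transition (A↔G or C↔T), Q the proportion differing by a transversion, over
the L sites comparable after the deletion policy. Then

    d_K2P  = -1/2 · ln((1 - 2P - Q) · sqrt(1 - 2Q))
    d_K2P+Γ = 1/2 · a(1-2P-Q) + 1/4 · a(1-2Q),  a(x) = α(x^(-1/α) - 1)

and TN93 splits transitions into purine (P1) and pyrimidine (P2) classes with
empirical base frequencies. Saturated pairs (log/power domain violations)
yield NaN flagged as undefined rather than raising, so large matrices degrade
gracefully.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .errors import NoOverlapError, ValidationError

#: nucleotide → index; anything else is treated as missing (excluded)
_CODE = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3}
MISSING = 4

_PURINES = (0, 2)  # A, G
_PYRIMIDINES = (1, 3)  # C, T


def encode_sequence(seq: str) -> np.ndarray:
    """Map a nucleotide string to uint8 codes; gaps/ambiguities become missing."""
    return np.array([_CODE.get(c, MISSING) for c in seq.upper()], dtype=np.uint8)


@dataclass(frozen=True)
class SpeciesAlignment:
    """Equal-length aligned sequences with a taxon → species assignment."""

    taxa: tuple[str, ...]
    sequences: tuple[str, ...]
    species_map: dict[str, str]

    def __post_init__(self) -> None:
        if len(self.taxa) != len(self.sequences):
            raise ValidationError(
                f"{len(self.taxa)} taxa but {len(self.sequences)} sequences"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValidationError("duplicate taxon ids in alignment")
        lengths = {len(s) for s in self.sequences}
        if len(lengths) > 1:
            raise ValidationError(f"unequal sequence lengths: {sorted(lengths)}")
        unmapped = [t for t in self.taxa if t not in self.species_map]
        if unmapped:
            raise ValidationError(f"taxa missing from species map: {unmapped}")

    @property
    def length(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def species_of(self, taxon: str) -> str:
        return self.species_map[taxon]

    def encoded(self) -> np.ndarray:
        """(n_taxa, L) uint8 matrix of nucleotide codes."""
        return np.vstack([encode_sequence(s) for s in self.sequences])


@dataclass(frozen=True)
class SiteCounts:
    """Site-pattern proportions for one sequence pair.

    P = transition proportion, split into purine (p_purine, A↔G) and
    pyrimidine (p_pyrimidine, C↔T) components; Q = transversion proportion;
    L = number of comparable sites. ``base_freqs`` are the empirical ACGT
    frequencies pooled over both sequences at the compared sites.
    """

    P: float
    Q: float
    L: int
    p_purine: float = 0.0
    p_pyrimidine: float = 0.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)


@dataclass(frozen=True)
class SubstModelParams:
    """Substitution-model parameters (TN93 family, optional discrete gamma).

    kappa_purine / kappa_pyrimidine are the A↔G and C↔T transition rate
    multipliers relative to the transversion rate; base_freqs must sum to 1.
    gamma_shape is the shape α of the gamma distribution of among-site rate
    variation, discretized into gamma_categories equal-probability classes.
    """

    kappa_purine: float = 5.0
    kappa_pyrimidine: float = 5.0
    base_freqs: tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    gamma_shape: float | None = None
    gamma_categories: int = 5

    def __post_init__(self) -> None:
        if abs(sum(self.base_freqs) - 1.0) > 1e-9:
            raise ValidationError(
                f"base frequencies sum to {sum(self.base_freqs)}, expected 1"
            )
        if self.gamma_shape is not None and self.gamma_shape <= 0:
            raise ValidationError("gamma shape must be > 0")
        if self.gamma_categories < 1:
            raise ValidationError("need at least one gamma category")


@dataclass(frozen=True)
class DistanceMatrix:
    """Symmetric pairwise distance matrix with per-cell defined flags."""

    taxa: tuple[str, ...]
    values: np.ndarray  # (n, n) float, NaN where undefined
    defined: np.ndarray = field(default=None)  # (n, n) bool

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.defined is None:
            object.__setattr__(self, "defined", ~np.isnan(self.values))
        if self.values.shape != (len(self.taxa), len(self.taxa)):
            raise ValidationError("matrix shape does not match taxon count")

    def get(self, a: str, b: str) -> float:
        i, j = self.taxa.index(a), self.taxa.index(b)
        return float(self.values[i, j])


def _comparable(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    return (a != MISSING) & (b != MISSING)


def count_site_patterns(
    seq_a: str | np.ndarray, seq_b: str | np.ndarray, deletion_policy: str = "pairwise"
) -> SiteCounts:
    """Count transition/transversion proportions for one sequence pair.

    Sites where either sequence has a gap or ambiguity are excluded
    (pairwise deletion). Alignment-wide policies ("complete", coverage
    cutoffs) are applied upstream by :func:`pairwise_matrix`.
    """
    a = encode_sequence(seq_a) if isinstance(seq_a, str) else seq_a
    b = encode_sequence(seq_b) if isinstance(seq_b, str) else seq_b
    if a.shape != b.shape:
        raise ValidationError(f"unequal sequence lengths: {a.size} vs {b.size}")
    if deletion_policy not in ("pairwise", "complete", "coverage"):
        raise ValidationError(f"unknown deletion policy: {deletion_policy!r}")

    keep = _comparable(a, b)
    L = int(keep.sum())
    if L == 0:
        raise NoOverlapError("no comparable sites between the two sequences")
    a, b = a[keep], b[keep]
    diff = a != b
    purine_ts = diff & np.isin(a, _PURINES) & np.isin(b, _PURINES)
    pyrimidine_ts = diff & np.isin(a, _PYRIMIDINES) & np.isin(b, _PYRIMIDINES)
    n_ts = int(purine_ts.sum() + pyrimidine_ts.sum())
    n_tv = int(diff.sum()) - n_ts

    pooled = np.concatenate([a, b])
    freqs = np.bincount(pooled, minlength=4)[:4] / (2 * L)
    return SiteCounts(
        P=n_ts / L,
        Q=n_tv / L,
        L=L,
        p_purine=float(purine_ts.sum()) / L,
        p_pyrimidine=float(pyrimidine_ts.sum()) / L,
        base_freqs=tuple(float(f) for f in freqs),
    )


def p_distance(counts: SiteCounts) -> float:
    """Raw proportion of differing sites."""
    return counts.P + counts.Q


def k2p_distance(counts: SiteCounts) -> float:
    """Kimura two-parameter distance; NaN when the pair is saturated."""
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan
    return -0.5 * math.log(w1 * math.sqrt(w2))


def gamma_corrected_distance(counts: SiteCounts, model: SubstModelParams) -> float:
    """K2P distance corrected for gamma rate heterogeneity of shape α.

    Replaces each -ln(x) of the K2P form with α(x^(-1/α) - 1); converges to
    the uncorrected distance as α → ∞ and exceeds it for finite α.
    """
    alpha = model.gamma_shape
    if alpha is None:
        return k2p_distance(counts)
    if alpha <= 0:
        raise ValidationError("gamma shape must be > 0")
    w1 = 1.0 - 2.0 * counts.P - counts.Q
    w2 = 1.0 - 2.0 * counts.Q
    if w1 <= 0.0 or w2 <= 0.0:
        return math.nan

    def a(x: float) -> float:
        return alpha * (x ** (-1.0 / alpha) - 1.0)

    return 0.5 * a(w1) + 0.25 * a(w2)


def tn93_distance(counts: SiteCounts) -> float:
    """Tamura–Nei distance from split transition proportions and frequencies.

    With equal base frequencies and equal purine/pyrimidine transition
    proportions this reduces exactly to the K2P distance.
    """
    pa, pc, pg, pt = counts.base_freqs
    pr, py = pa + pg, pc + pt
    if pa * pg <= 0 or pt * pc <= 0:
        # a zero-frequency base makes a transition class term undefined
        return math.nan
    k1 = 2.0 * pa * pg / pr
    k2 = 2.0 * pt * pc / py
    k3 = 2.0 * (pr * py - pa * pg * py / pr - pt * pc * pr / py)
    w1 = 1.0 - counts.p_purine / k1 - counts.Q / (2.0 * pr)
    w2 = 1.0 - counts.p_pyrimidine / k2 - counts.Q / (2.0 * py)
    w3 = 1.0 - counts.Q / (2.0 * pr * py)
    if w1 <= 0 or w2 <= 0 or w3 <= 0:
        return math.nan
    return -k1 * math.log(w1) - k2 * math.log(w2) - k3 * math.log(w3)


_MODEL_FUNCS = {
    "p": lambda c, m: p_distance(c),
    "k2p": lambda c, m: k2p_distance(c),
    "tn93": lambda c, m: tn93_distance(c),
    "k2p+g": gamma_corrected_distance,
}


def _column_mask(encoded: np.ndarray, deletion_policy: str, coverage: float) -> np.ndarray:
    """Columns retained before pairwise comparison, per alignment-wide policy."""
    present = encoded != MISSING
    if deletion_policy == "pairwise":
        return np.ones(encoded.shape[1], dtype=bool)
    if deletion_policy == "complete":
        return present.all(axis=0)
    if deletion_policy == "coverage":
        return present.mean(axis=0) >= coverage
    raise ValidationError(f"unknown deletion policy: {deletion_policy!r}")


def pairwise_matrix(
    alignment: SpeciesAlignment,
    model: str = "k2p",
    deletion_policy: str = "pairwise",
    *,
    coverage: float = 0.95,
    model_params: SubstModelParams | None = None,
) -> DistanceMatrix:
    """All-pairs distance matrix under the chosen model and deletion policy.

    Saturated or non-overlapping pairs become NaN cells flagged undefined.
    """
    if len(alignment.taxa) < 2:
        raise ValidationError("need at least two taxa")
    if model not in _MODEL_FUNCS:
        raise ValidationError(f"unknown model {model!r}; choose from {sorted(_MODEL_FUNCS)}")
    if model == "k2p+g" and (model_params is None or model_params.gamma_shape is None):
        raise ValidationError("k2p+g requires model_params with a gamma shape")

    enc = alignment.encoded()
    enc = enc[:, _column_mask(enc, deletion_policy, coverage)]
    n = len(alignment.taxa)
    vals = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            try:
                counts = count_site_patterns(enc[i], enc[j])
                d = _MODEL_FUNCS[model](counts, model_params)
            except NoOverlapError:
                d = math.nan
            vals[i, j] = vals[j, i] = d
    return DistanceMatrix(taxa=alignment.taxa, values=vals)


def group_mean_distance(
    matrix: DistanceMatrix, species_map: dict[str, str]
):
    """Between-species mean distances, plus within-species means.

    Returns ``(between, within)``: ``between`` is a pandas DataFrame whose
    (A, B) cell is the arithmetic mean distance over all cross-species taxon
    pairs; ``within`` maps each species to its mean intra-species distance
    (NaN for singleton species). Undefined cross cells raise with the
    offending pairs listed.
    """
    import pandas as pd

    unmapped = [t for t in matrix.taxa if t not in species_map]
    if unmapped:
        raise ValidationError(f"taxa missing from species map: {unmapped}")
    species = sorted(set(species_map[t] for t in matrix.taxa))
    members = {s: [i for i, t in enumerate(matrix.taxa) if species_map[t] == s] for s in species}

    bad = []
    between = pd.DataFrame(0.0, index=species, columns=species)
    within = {}
    for si, s_a in enumerate(species):
        ia = members[s_a]
        intra = [
            matrix.values[i, j] for k, i in enumerate(ia) for j in ia[k + 1:]
        ]
        within[s_a] = float(np.mean(intra)) if intra else math.nan
        for s_b in species[si + 1:]:
            cells = [(i, j) for i in ia for j in members[s_b]]
            vals = [matrix.values[i, j] for i, j in cells]
            for (i, j), v in zip(cells, vals):
                if math.isnan(v):
                    bad.append((matrix.taxa[i], matrix.taxa[j]))
            m = float(np.mean(vals))
            between.loc[s_a, s_b] = between.loc[s_b, s_a] = m
    if bad:
        raise ValidationError(f"undefined distances for pairs: {bad}")
    return between, within
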