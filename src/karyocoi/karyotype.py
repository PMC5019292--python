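"""Chromosome-arm metrics, Levan morphology classes and karyotype summaries.

A karyotype is described from per-chromosome-pair arm measurements: for each
pair the long-arm length (LA) and short-arm length (SA) in µm. From these the
arm ratio r = LA/SA and the centromeric index CI = SA/(LA+SA) are derived and
each chromosome is assigned one of the four Levan morphology classes

    m  (metacentric)      1.0 ≤ r ≤ 1.7
    sm (submetacentric)   1.7 < r ≤ 3.0
    st (subtelocentric)   3.0 < r ≤ 7.0
    t  (telocentric)            r > 7.0

with boundary values assigned to the more metacentric class. The karyotype
summary reports the diploid number 2n, chromosome counts per class (twice the
pair counts), the canonical formula string (e.g. "4m+40sm+6st") and the
fundamental number NF = 2·(m + sm) + (st + t): bi-armed chromosomes contribute
two arms, one-armed chromosomes one.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

from .errors import ValidationError

MORPH_CLASSES = ("m", "sm", "st", "t")

#: Upper arm-ratio bound of each class; boundary goes to the lower class.
CLASS_BOUNDS = {"m": 1.7, "sm": 3.0, "st": 7.0, "t": float("inf")}

#: Classes whose short arm is distinct enough to count as a second arm.
BIARMED_CLASSES = ("m", "sm")


@dataclass(frozen=True)
class ArmMeasurement:
    """One chromosome pair's arm lengths in µm (long ≥ short > 0)."""

    pair_id: int
    long_arm: float
    short_arm: float

    def __post_init__(self) -> None:
        if self.short_arm <= 0:
            raise ValidationError(
                f"pair {self.pair_id}: short arm must be > 0, got {self.short_arm}"
            )
        if self.long_arm < self.short_arm:
            raise ValidationError(
                f"pair {self.pair_id}: long arm ({self.long_arm}) shorter than "
                f"short arm ({self.short_arm})"
            )


@dataclass(frozen=True)
class ChromosomeMetrics:
    """Derived per-chromosome quantities; satisfies CI = 1/(1 + r)."""

    pair_id: int
    long_arm: float
    short_arm: float
    total_len: float
    arm_ratio: float
    centromeric_index: float
    morph_class: str | None = None


@dataclass(frozen=True)
class KaryotypeSummary:
    species_label: str
    n_pairs: int
    diploid_number: int
    class_counts: dict[str, int]
    formula: str
    fundamental_number: int


def compute_metrics(measurement: ArmMeasurement) -> ChromosomeMetrics:
    """Derive total length, arm ratio and centromeric index for one pair.

    No rounding is applied here; values are rounded only at presentation
    time (see :func:`round2`).
    """
    total = measurement.long_arm + measurement.short_arm
    return ChromosomeMetrics(
        pair_id=measurement.pair_id,
        long_arm=measurement.long_arm,
        short_arm=measurement.short_arm,
        total_len=total,
        arm_ratio=measurement.long_arm / measurement.short_arm,
        centromeric_index=measurement.short_arm / total,
    )


def classify(arm_ratio: float) -> str:
    """Assign the Levan morphology class for an arm ratio r ≥ 1."""
    if arm_ratio < 1.0:
        raise ValidationError(f"arm ratio must be ≥ 1, got {arm_ratio}")
    for cls, upper in CLASS_BOUNDS.items():
        if arm_ratio <= upper:
            return cls
    raise AssertionError("unreachable")  # pragma: no cover


def fundamental_number(class_counts: dict[str, int]) -> int:
    """Arm count NF = 2·(m + sm) + (st + t) from chromosome class counts.

    Counts are chromosome counts (not pair counts) and must therefore be
    even and nonnegative.
    """
    counts = {c: int(class_counts.get(c, 0)) for c in MORPH_CLASSES}
    for cls, n in counts.items():
        if n < 0:
            raise ValidationError(f"negative count for class {cls}: {n}")
        if n % 2:
            raise ValidationError(
                f"class {cls} count {n} is odd; chromosome counts come in pairs"
            )
    biarmed = sum(counts[c] for c in BIARMED_CLASSES)
    one_armed = sum(counts[c] for c in MORPH_CLASSES if c not in BIARMED_CLASSES)
    return 2 * biarmed + one_armed


def karyotype_formula(class_counts: dict[str, int]) -> str:
    """Canonical formula string: zero classes omitted, order m, sm, st, t."""
    parts = [
        f"{class_counts[c]}{c}"
        for c in MORPH_CLASSES
        if class_counts.get(c, 0) > 0
    ]
    return "+".join(parts)


def summarize_karyotype(
    measurements: list[ArmMeasurement],
    species_label: str = "",
    *,
    arm_ratios: list[float] | None = None,
) -> KaryotypeSummary:
    """Summarize a species karyotype from its per-pair measurements.

    Parameters
    ----------
    measurements
        One entry per chromosome pair, unique ``pair_id`` each.
    species_label
        Free-text label carried into the summary.
    arm_ratios
        Optional externally supplied arm ratios (one per measurement, same
        order) to classify on instead of ratios recomputed from the arms —
        used when a published table's printed AR column is the authority.
    """
    if not measurements:
        raise ValidationError("no measurements supplied")
    ids = [m.pair_id for m in measurements]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate pair ids: {dupes}")
    if arm_ratios is not None and len(arm_ratios) != len(measurements):
        raise ValidationError(
            f"{len(arm_ratios)} arm ratios for {len(measurements)} measurements"
        )

    counts = {c: 0 for c in MORPH_CLASSES}
    for i, meas in enumerate(measurements):
        r = arm_ratios[i] if arm_ratios is not None else compute_metrics(meas).arm_ratio
        counts[classify(r)] += 2  # a pair contributes two chromosomes

    return KaryotypeSummary(
        species_label=species_label,
        n_pairs=len(measurements),
        diploid_number=sum(counts.values()),
        class_counts=counts,
        formula=karyotype_formula(counts),
        fundamental_number=fundamental_number(counts),
    )


def round2(value: float) -> float:
    """Round to 2 decimals, half away from zero, for report output."""
    return float(Decimal(repr(value)).quantize(Decimal("0.01"), ROUND_HALF_UP))
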