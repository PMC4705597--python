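"""Copy-number-aware genotype calling from raw assay signals.

Two channels feed the pipeline: competitive allele-specific PCR (KASP)
endpoint fluorescence, where each allele reports through one fluorophore
(VIC for the X allele, FAM for Y) and the genotype is read from the
position of the point on the two-dimensional intensity plane; and qPCR
Cq values converted to genome equivalents against a single-copy internal
control and a disomic calibrator.

A normal biallelic SNP yields three fluorescence clusters (XX, YY, XY)
plus the no-template origin.  Over a segment that is duplicated on some
chromosomes, two extra clusters appear at allele ratios 2:1 and 1:2 —
three amplifiable targets in a diploid — and deleted segments collapse
into the fail cluster at the origin.  Classification is nearest-centroid
with a fixed rejection radius; points no centroid claims are UNDEFINED.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .panel import GenotypeCall, GenotypeMatrix, SNPPanel
from .simulate import KASP_CENTROIDS

__all__ = [
    "FluorescencePoint",
    "GenomeEquivalent",
    "NO_AMPLIFICATION",
    "classify_kasp_point",
    "genome_equivalents",
    "call_matrix_from_fluorescence",
    "DEFAULT_CENTROIDS",
    "DEFAULT_MAX_RADIUS",
]

#: Default cluster centroids: the geometric six-code model on the
#: normalized (vic, fam) plane.
DEFAULT_CENTROIDS: dict[GenotypeCall, tuple[float, float]] = {
    c: v for c, v in KASP_CENTROIDS.items() if c != GenotypeCall.AMBIG_BOTH
}

#: Rejection radius on the normalized plane.  Points farther than this
#: from every centroid are aberrant chemistry (undefined), not noisy
#: cluster members; 0.2 is ~4 sd of typical endpoint noise while still
#: exceeding half the minimal inter-centroid distance, so gating never
#: flips a call, it only rejects outliers.
DEFAULT_MAX_RADIUS = 0.2


@dataclass(frozen=True)
class FluorescencePoint:
    vic: float
    fam: float
    sample_id: str = ""
    is_ntc: bool = False

    def __post_init__(self) -> None:
        if not (math.isfinite(self.vic) and math.isfinite(self.fam)):
            raise ValueError("fluorescence intensities must be finite")
        if self.vic < 0 or self.fam < 0:
            raise ValueError("fluorescence intensities must be nonnegative")


class _NoAmplification:
    def __repr__(self) -> str:  # pragma: no cover
        return "NO_AMPLIFICATION"


#: Sentinel for a qPCR target that never amplified (zero-copy segment).
NO_AMPLIFICATION = _NoAmplification()


@dataclass(frozen=True)
class GenomeEquivalent:
    """Relative copy number (1.0 = disomic) or NO_AMPLIFICATION."""

    value: float | _NoAmplification
    sample_id: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.value, _NoAmplification) and self.value < 0:
            raise ValueError("genome equivalents must be nonnegative")

    @property
    def amplified(self) -> bool:
        return not isinstance(self.value, _NoAmplification)


def classify_kasp_point(
    p: FluorescencePoint,
    centroids: dict[GenotypeCall, tuple[float, float]] | None = None,
    max_radius: float = DEFAULT_MAX_RADIUS,
) -> GenotypeCall:
    """Nearest-centroid call on the normalized plane, UNDEFINED outside
    ``max_radius`` of every centroid."""
    if centroids is None:
        centroids = DEFAULT_CENTROIDS
    if not centroids:
        raise ValueError("empty centroid map")
    best, best_d = None, math.inf
    for code in sorted(centroids, key=lambda c: c.value):
        cv, cf = centroids[code]
        d = math.hypot(p.vic - cv, p.fam - cf)
        if d < best_d:
            best, best_d = code, d
    if best_d > max_radius:
        return GenotypeCall.UNDEFINED
    return best


def _mean_cq(cqs: list[float], label: str) -> float:
    """Replicate aggregation: arithmetic mean after dropping outliers more
    than 1.5 Cq from the median."""
    if not cqs:
        raise ValueError(f"no {label} replicates")
    med = float(np.median(cqs))
    kept = [c for c in cqs if abs(c - med) <= 1.5]
    if len(kept) < len(cqs):
        warnings.warn(
            f"dropped {len(cqs) - len(kept)} outlier {label} replicate(s) "
            f"(>1.5 Cq from median)",
            stacklevel=3,
        )
    return float(np.mean(kept))


def genome_equivalents(
    target_cqs: list[float],
    control_cqs: list[float],
    calibrator: tuple[list[float], list[float]],
    efficiency: float = 2.0,
    sample_id: str = "",
) -> GenomeEquivalent:
    """Relative genome equivalents by the ddCq method.

    value = eff ** -(dCq_sample - dCq_calibrator), with dCq = mean(target
    Cq) - mean(control Cq).  Normalization to the single-copy control
    removes input-quantity differences; normalization to the disomic
    calibrator puts the result on the genome-equivalent scale (disomic =
    1.0).  An all-missing target means the segment is absent.
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must be in (1, 2]")
    if not control_cqs:
        raise ValueError("missing control replicates")
    cal_t, cal_c = calibrator
    dcq_cal = _mean_cq(cal_t, "calibrator target") - _mean_cq(
        cal_c, "calibrator control"
    )
    if not target_cqs:
        return GenomeEquivalent(value=NO_AMPLIFICATION, sample_id=sample_id)
    dcq = _mean_cq(target_cqs, "target") - _mean_cq(control_cqs, "control")
    value = efficiency ** -(dcq - dcq_cal)
    return GenomeEquivalent(value=float(value), sample_id=sample_id)


def call_matrix_from_fluorescence(
    points: list[list[FluorescencePoint]],
    panel: SNPPanel,
    bird_ids: list[str],
    line_ids: list[str] | None = None,
    centroids: dict[GenotypeCall, tuple[float, float]] | None = None,
    max_radius: float = DEFAULT_MAX_RADIUS,
) -> GenotypeMatrix:
    """Classify a rectangular bird x SNP grid of fluorescence points.

    Over core SNPs the duplication clusters collapse to AMBIG_BOTH (the
    haplotype analysis treats "both alleles" as one state); over flank
    SNPs the DUP codes are kept.  NTC points are forced to FAIL.
    """
    n_birds, n_snps = len(points), len(panel)
    if len(bird_ids) != n_birds:
        raise ValueError("bird_ids length does not match grid")
    for r, row in enumerate(points):
        if len(row) != n_snps:
            raise ValueError(
                f"row {r} has {len(row)} points, expected {n_snps}"
            )
    calls = np.empty((n_birds, n_snps), dtype=object)
    for i, row in enumerate(points):
        for j, p in enumerate(row):
            if p.is_ntc:
                calls[i, j] = GenotypeCall.FAIL
                continue
            c = classify_kasp_point(p, centroids, max_radius)
            if panel.snps[j].in_core and c in (
                GenotypeCall.DUP_XXY, GenotypeCall.DUP_XYY
            ):
                c = GenotypeCall.AMBIG_BOTH
            calls[i, j] = c
    return GenotypeMatrix(
        panel=panel,
        bird_ids=list(bird_ids),
        line_ids=list(line_ids) if line_ids is not None else ["?"] * n_birds,
        calls=calls,
    )
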