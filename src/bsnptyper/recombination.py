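"""Recombinant haplotype detection, breakpoint localization, hotspot
profiling and rate estimation.

A recombinant haplotype matches one parental haplotype over a 5' prefix
of the core SNPs and a second over the complementary 3' suffix.  A
candidate is scored as recombinant only when BOTH parental haplotypes are
present in the same population — candidates for which only one parent can
be identified go to a separate "apparent recombination" report.  Because
crossovers fall within runs of sequence identical between the two
parents, a breakpoint is localized only to the interval between the last
informative SNP matching the 5' parent and the first informative SNP
matching the 3' parent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .panel import Allele, GenotypeMatrix, Haplotype, SNPPanel
from .phasing import HaplotypeSet

__all__ = [
    "RecombinantCall",
    "ApparentRecombinant",
    "HotspotProfile",
    "RateEstimate",
    "LeiMutationEvent",
    "detect_recombinants",
    "localize_breakpoint",
    "hotspot_profile",
    "recombination_rate",
    "lei0258_mutation_rate",
    "detect_pedigree_mutations",
]


@dataclass(frozen=True)
class RecombinantCall:
    recombinant: Haplotype
    parent_5prime: Haplotype
    parent_3prime: Haplotype
    interval_start_bp: int
    interval_end_bp: int
    #: (snp_name, observed rendering, kind) — kind "mutation" for an
    #: allele found in neither parent (counted against max_mismatches),
    #: "deletion" for a shared assay failure with one parent (annotated,
    #: not counted)
    mismatches: tuple[tuple[str, str, str], ...]
    name: str

    def __post_init__(self) -> None:
        if self.interval_start_bp >= self.interval_end_bp:
            raise ValueError("breakpoint interval must have positive width")
        if self.parent_5prime.key == self.parent_3prime.key:
            raise ValueError("parental haplotypes must be distinct")


@dataclass(frozen=True)
class ApparentRecombinant:
    """A mosaic-looking haplotype whose second parent is absent from the
    population; excluded from recombinant calls and rates."""

    candidate: Haplotype
    matched_parent: Haplotype | None


@dataclass
class HotspotProfile:
    bin_size_bp: int
    counts: np.ndarray          # per-bin unique-recombinant coverage
    hotspot_threshold: int
    hotspots: list[tuple[int, int]] = field(default_factory=list)
    letters: list[str] = field(default_factory=list)

    def bin_start(self, i: int) -> int:
        return i * self.bin_size_bp


@dataclass(frozen=True)
class RateEstimate:
    events: int
    denominator: int
    per_unit: int
    rate: float
    ci95: tuple[float, float]
    #: events whose size change is not a multiple of 12 or 13 bp
    flagged: tuple[int, ...] = ()

    @property
    def rounded(self) -> float:
        """The rate as reported, to one decimal."""
        return round(self.rate, 1)


def _informative(p5: Haplotype, p3: Haplotype) -> list[int]:
    return [
        i
        for i, (a, b) in enumerate(zip(p5.alleles, p3.alleles))
        if a != Allele.MISSING and b != Allele.MISSING and a != b
    ]


def _mosaic_cost(
    cand: Haplotype, p5: Haplotype, p3: Haplotype
) -> tuple[int, int] | None:
    """Minimal mismatch count over all single-breakpoint splits, and the
    best split index (prefix = indices < split).

    A mismatch is a site where the candidate and the expected parent are
    both non-missing and differ.  Requires the candidate to match each
    parent at >= 1 informative site on its own side (a genuine mosaic);
    returns None otherwise.
    """
    n = len(cand)
    d5 = np.zeros(n, dtype=int)
    d3 = np.zeros(n, dtype=int)
    for i in range(n):
        c = cand.alleles[i]
        if c != Allele.MISSING:
            if p5.alleles[i] != Allele.MISSING and c != p5.alleles[i]:
                d5[i] = 1
            if p3.alleles[i] != Allele.MISSING and c != p3.alleles[i]:
                d3[i] = 1
    pre = np.concatenate([[0], np.cumsum(d5)])
    suf = np.concatenate([np.cumsum(d3[::-1])[::-1], [0]])
    costs = pre + suf
    info = _informative(p5, p3)
    best = None
    for k in range(n + 1):
        m5 = any(
            i < k and cand.alleles[i] == p5.alleles[i] != Allele.MISSING
            and cand.alleles[i] != Allele.MISSING
            for i in info
        )
        m3 = any(
            i >= k and cand.alleles[i] == p3.alleles[i]
            and cand.alleles[i] != Allele.MISSING
            for i in info
        )
        if m5 and m3:
            if best is None or costs[k] < costs[best]:
                best = k
    if best is None:
        return None
    return int(costs[best]), int(best)


def localize_breakpoint(
    rec: Haplotype, p5: Haplotype, p3: Haplotype, panel: SNPPanel
) -> tuple[int, int]:
    """Breakpoint ambiguity interval of a single-breakpoint mosaic.

    Start = position of the last informative SNP (parents differ, calls
    present) where the recombinant matches the 5' parent; end = position
    of the first later informative SNP where it matches the 3' parent.
    SNPs in between — where the parents are identical or a call is
    missing — cannot narrow the crossover further.
    """
    pos = panel.core_positions
    info = _informative(p5, p3)
    m5 = [
        i for i in info
        if rec.alleles[i] != Allele.MISSING and rec.alleles[i] == p5.alleles[i]
    ]
    if not m5:
        raise ValueError("no informative site matches the 5' parent")
    i_last = max(m5)
    m3 = [
        j for j in info
        if j > i_last
        and rec.alleles[j] != Allele.MISSING
        and rec.alleles[j] == p3.alleles[j]
    ]
    if not m3:
        raise ValueError(
            "recombinant matches one parent at every informative site; "
            "no breakpoint"
        )
    return int(pos[i_last]), int(pos[min(m3)])


def _render_allele(a: Allele) -> str:
    return {Allele.X: "X", Allele.Y: "Y", Allele.BOTH: "BOTH",
            Allele.MISSING: "F"}[a]


def detect_recombinants(
    candidates: HaplotypeSet,
    population_haps: HaplotypeSet,
    panel: SNPPanel,
    max_mismatches: int = 1,
    name_start: int = 1,
) -> tuple[list[RecombinantCall], list[ApparentRecombinant]]:
    """Scan candidate haplotypes for single-breakpoint mosaics of two
    population haplotypes.

    For each candidate absent from ``population_haps``, all ordered
    parent pairs are searched; among pairs within ``max_mismatches`` the
    one minimizing mismatches, then maximizing the breakpoint-interval
    width, is reported.  Names BSNP-RecNN follow detection order.
    """
    pop_keys = {h.key for h in population_haps.haplotypes}
    snp_names = [s.name for s in panel.core_snps]
    calls: list[RecombinantCall] = []
    apparent: list[ApparentRecombinant] = []
    n_named = name_start
    for cand in candidates.haplotypes:
        if cand.key in pop_keys:
            continue
        best = None  # (mismatches, -width, p5_idx, p3_idx, split)
        for i5, p5 in enumerate(population_haps.haplotypes):
            for i3, p3 in enumerate(population_haps.haplotypes):
                if p5.key == p3.key:
                    continue
                res = _mosaic_cost(cand, p5, p3)
                if res is None:
                    continue
                cost, split = res
                if cost > max_mismatches:
                    continue
                try:
                    lo, hi = localize_breakpoint(cand, p5, p3, panel)
                except ValueError:
                    continue
                key = (cost, -(hi - lo), i5, i3, split, lo, hi)
                if best is None or key < best:
                    best = key
        if best is None:
            # one-parent partial matches -> apparent recombination report
            one = None
            for p in population_haps.haplotypes:
                shared = [
                    i for i, (a, b) in enumerate(zip(cand.alleles, p.alleles))
                    if a != Allele.MISSING and b != Allele.MISSING
                ]
                if shared and all(
                    cand.alleles[i] == p.alleles[i]
                    for i in shared[: len(shared) // 2]
                ):
                    one = p
                    break
            apparent.append(ApparentRecombinant(candidate=cand, matched_parent=one))
            continue
        cost, _negw, i5, i3, split, lo, hi = best
        p5 = population_haps.haplotypes[i5]
        p3 = population_haps.haplotypes[i3]
        mismatches: list[tuple[str, str, str]] = []
        for i in range(len(cand)):
            expected = p5.alleles[i] if i < split else p3.alleles[i]
            c = cand.alleles[i]
            if (
                c != Allele.MISSING
                and expected != Allele.MISSING
                and c != expected
            ):
                # allele in neither parent suggests a point mutation; an
                # out-of-place match to the other parent is merely discordant
                kind = (
                    "mutation"
                    if c not in (p5.alleles[i], p3.alleles[i])
                    else "discordant"
                )
                mismatches.append((snp_names[i], _render_allele(c), kind))
            elif c == Allele.MISSING and expected == Allele.MISSING:
                mismatches.append((snp_names[i], "F", "deletion"))
        calls.append(
            RecombinantCall(
                recombinant=cand,
                parent_5prime=p5,
                parent_3prime=p3,
                interval_start_bp=lo,
                interval_end_bp=hi,
                mismatches=tuple(mismatches),
                name=f"BSNP-Rec{n_named:02d}",
            )
        )
        n_named += 1
    return calls, apparent


def hotspot_profile(
    calls: list[RecombinantCall] | list[tuple[int, int]],
    panel: SNPPanel,
    bin_size: int = 1000,
    threshold: int = 4,
    mode: str = "contained",
) -> HotspotProfile:
    """Per-1000-bp coverage of breakpoint intervals and hotspot runs.

    Each unique recombinant haplotype contributes once (duplicate calls
    for the same recombinant are collapsed; plain (start, end) interval
    tuples are assumed pre-deduplicated and counted as given).  A bin is
    counted when it is fully contained in the breakpoint interval
    (``mode='contained'``: each 1000-bp segment contained within the
    putative recombination region) or on any overlap (``mode='overlap'``).
    Bins tile the reference from coordinate 0.  Hotspots are maximal runs
    of bins with count >= ``threshold``, lettered A, B, ... left to right.
    """
    if bin_size <= 0:
        raise ValueError("bin_size must be positive")
    if mode not in ("contained", "overlap"):
        raise ValueError(f"unknown mode {mode!r}")
    n_bins = -(-panel.reference_length // bin_size)
    counts = np.zeros(n_bins, dtype=int)
    seen: set = set()
    for ci, c in enumerate(calls):
        if isinstance(c, RecombinantCall):
            key = c.recombinant.key
            lo, hi = c.interval_start_bp, c.interval_end_bp
        else:
            lo, hi = c
            key = ci
        if key in seen:
            continue
        seen.add(key)
        if mode == "contained":
            first = -(-lo // bin_size)           # ceil(lo / bin)
            last = hi // bin_size                # bins with end <= hi
            counts[first:last] += 1
        else:
            first = lo // bin_size
            last = -(-hi // bin_size)
            counts[first:last] += 1
    profile = HotspotProfile(
        bin_size_bp=bin_size, counts=counts, hotspot_threshold=threshold
    )
    hot = counts >= threshold
    i = 0
    letter = 0
    while i < n_bins:
        if hot[i]:
            j = i
            while j + 1 < n_bins and hot[j + 1]:
                j += 1
            profile.hotspots.append((i * bin_size, (j + 1) * bin_size))
            profile.letters.append(chr(ord("A") + letter))
            letter += 1
            i = j + 1
        else:
            i += 1
    return profile


def _binomial_rate(
    events: int, denominator: int, per_unit: int,
    flagged: tuple[int, ...] = (),
) -> RateEstimate:
    if denominator <= 0:
        raise ValueError("denominator must be positive")
    if not (0 <= events <= denominator):
        raise ValueError("events must be in 0..denominator")
    # exact (Clopper-Pearson) 95% CI on the proportion
    alpha = 0.05
    lo = 0.0 if events == 0 else float(
        stats.beta.ppf(alpha / 2, events, denominator - events + 1)
    )
    hi = 1.0 if events == denominator else float(
        stats.beta.ppf(1 - alpha / 2, events + 1, denominator - events)
    )
    return RateEstimate(
        events=events,
        denominator=denominator,
        per_unit=per_unit,
        rate=per_unit * events / denominator,
        ci95=(per_unit * lo, per_unit * hi),
        flagged=flagged,
    )


def recombination_rate(n_events: int, n_birds: int) -> RateEstimate:
    """Crossovers per 100 birds with an exact binomial 95% CI."""
    return _binomial_rate(n_events, n_birds, per_unit=100)


def lei0258_mutation_rate(
    events: list[int], n_birds: int
) -> RateEstimate:
    """LEI0258 allele-size mutations per 1000 birds.

    ``events`` are observed size changes in bp; changes that are not a
    multiple of a 12- or 13-bp repeat unit are flagged but still counted.
    """
    flagged = tuple(
        e for e in events
        if not (e != 0 and (e % 12 == 0 or e % 13 == 0 or (-e) % 12 == 0 or (-e) % 13 == 0))
    )
    return _binomial_rate(len(events), n_birds, per_unit=1000, flagged=flagged)


@dataclass(frozen=True)
class LeiMutationEvent:
    bird_id: str
    allele_size: int
    nearest_parental: int
    delta: int


def detect_pedigree_mutations(m: GenotypeMatrix) -> list[LeiMutationEvent]:
    """LEI0258 alleles in offspring not attributable to either parent.

    An offspring is consistent when one of its alleles can come from the
    sire and the other from the dam; otherwise each unattributable allele
    is an event, recorded with its signed distance to the nearest
    parental allele.  Offspring with missing LEI0258 data (own or
    parental) are skipped.
    """
    if not m.pedigree:
        raise ValueError("genotype matrix carries no pedigree")
    events: list[LeiMutationEvent] = []
    for bird, (sire, dam) in sorted(m.pedigree.items()):
        if bird not in m.lei0258 or sire not in m.lei0258 or dam not in m.lei0258:
            continue
        x, y = m.lei0258[bird]
        s = m.lei0258[sire]
        d = m.lei0258[dam]
        if (x in s and y in d) or (x in d and y in s):
            continue
        parental = sorted(set(s) | set(d))
        for allele in (x, y):
            if allele not in parental:
                nearest = min(parental, key=lambda p: (abs(allele - p), p))
                events.append(
                    LeiMutationEvent(
                        bird_id=bird,
                        allele_size=allele,
                        nearest_parental=nearest,
                        delta=allele - nearest,
                    )
                )
    return events
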