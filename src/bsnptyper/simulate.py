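"""Synthetic MHC-B populations with known truth.

The generator emulates the statistical structure the downstream analysis
assumes: a 101-SNP panel (90 haplotype-defining "core" SNPs spanning
30,189–240,933 bp plus 11 5' SNPs in a copy-number-variable region), a few
well-separated haplotype families segregating within commercial lines, a
fully pedigreed sire/dam/offspring cross with rare single-crossover
recombination concentrated in hotspot regions, LEI0258 VNTR alleles that
mutate in 12/13-bp repeat steps, and per-haplotype duplication/deletion of
the 5' *BG2* segment that produces dual-allele and fail genotype codes.

Every stochastic choice flows from ``SimConfig.seed`` through one
``numpy.random.Generator``; identical configs give identical outputs.
"""

from __future__ import annotations

import string
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .panel import (
    Allele,
    GenotypeCall,
    GenotypeMatrix,
    Haplotype,
    SNPDef,
    SNPPanel,
)

__all__ = [
    "SimConfig",
    "TruthTable",
    "CrossoverTruth",
    "LeiMutationTruth",
    "default_panel",
    "generate_founder_haplotypes",
    "simulate_population",
    "simulate_kasp_fluorescence",
    "simulate_qpcr",
    "KASP_CENTROIDS",
    "LEI_POSITION_BP",
    "CNV_SEGMENT_BP",
]

#: Approximate position of the LEI0258 VNTR on the AB268588 interval (it
#: lies between the class II and class I subregions; used only to decide
#: which parental chromosome contributes the VNTR allele to a recombinant).
LEI_POSITION_BP = 128_500

#: Default copy-number-variable segment: the MHCNew07–MHCNew12 span within
#: the BG2 gene.
CNV_SEGMENT_BP = (12_062, 13_992)

#: LEI0258 allele sizes (bp, ABI-377 scale) observed across standard
#: haplotypes; families draw their base allele from this palette.
_LEI_PALETTE = (
    182, 193, 205, 249, 261, 295, 307, 309, 319, 345,
    357, 369, 393, 405, 443, 461, 474, 487, 539, 552,
)

#: Noiseless endpoint-fluorescence centroids, (vic, fam) = (X-signal,
#: Y-signal) on the normalized plane.  The five informative clusters plus
#: the no-amplification origin.
KASP_CENTROIDS: dict[GenotypeCall, tuple[float, float]] = {
    GenotypeCall.XX: (1.0, 0.0),
    GenotypeCall.YY: (0.0, 1.0),
    GenotypeCall.XY: (0.5, 0.5),
    GenotypeCall.AMBIG_BOTH: (0.5, 0.5),
    GenotypeCall.DUP_XXY: (2.0 / 3.0, 1.0 / 3.0),
    GenotypeCall.DUP_XYY: (1.0 / 3.0, 2.0 / 3.0),
    GenotypeCall.FAIL: (0.0, 0.0),
}


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for one synthetic population.

    Defaults follow the surveyed pedigreed cross: 1189 offspring from 15
    sires x 142 dams, a recombination rate of 0.006 per bird, and LEI0258
    mutating at 1.1 per 1000 birds in 12/13-bp steps.
    """

    n_core_snps: int = 90
    n_flank_snps: int = 11
    n_families: int = 4
    haps_per_family: int = 2
    within_family_diff: int = 3
    between_family_diff: int = 30
    n_lines: int = 1
    haps_per_line: int = 2
    n_sires: int = 15
    n_dams: int = 142
    n_offspring: int = 1189
    #: probability that an offspring carries one recombinant haplotype
    #: (one crossover in one of its two parental transmissions)
    recomb_rate_per_offspring: float = 0.006
    #: crossover-position mass: (start_bp, end_bp, weight) bins; default
    #: puts 80% of mass in the recombination-rich 35–100 kb region and the
    #: rest across the remaining core span
    hotspot_bins: tuple[tuple[int, int, float], ...] = (
        (35_000, 100_000, 0.8),
        (30_189, 35_000, 0.2 * (35_000 - 30_189) / (240_933 - 100_000 + 35_000 - 30_189)),
        (100_000, 240_933, 0.2 * (240_933 - 100_000) / (240_933 - 100_000 + 35_000 - 30_189)),
    )
    lei_mutation_rate: float = 0.0011
    lei_step_sizes: tuple[int, ...] = (12, 13)
    lei_up_bias: float = 1.0  # all observed pedigreed mutations were size increases
    #: founder index -> copies of the 5' CNV segment (0, 1 or 2); None =>
    #: drawn per founder with probabilities ~(0.19, 0.66, 0.15), matching
    #: the observed fractions of fail / normal / dual-allele haplotypes
    cnv_haplotype_profile: dict[int, int] | None = None
    fluor_noise_sd: float = 0.03
    qpcr_noise_sd: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (0.0 <= self.recomb_rate_per_offspring <= 1.0):
            raise ValueError("recomb_rate_per_offspring must be in [0,1]")
        if not (0.0 <= self.lei_mutation_rate <= 1.0):
            raise ValueError("lei_mutation_rate must be in [0,1]")
        if not self.hotspot_bins or all(w <= 0 for _, _, w in self.hotspot_bins):
            raise ValueError("hotspot_bins needs at least one positive weight")
        if any(w < 0 for _, _, w in self.hotspot_bins):
            raise ValueError("hotspot bin weights must be nonnegative")
        if self.between_family_diff <= self.within_family_diff:
            raise ValueError("between_family_diff must exceed within_family_diff")
        if self.fluor_noise_sd < 0 or self.qpcr_noise_sd < 0:
            raise ValueError("noise sd must be nonnegative")


@dataclass(frozen=True)
class CrossoverTruth:
    offspring_id: str
    parent_role: str          # "sire" or "dam": which transmission recombined
    position_bp: int
    founder_5prime: int       # founder index contributing the 5' prefix
    founder_3prime: int


@dataclass(frozen=True)
class LeiMutationTruth:
    offspring_id: str
    parent_role: str
    parental_size: int
    new_size: int


@dataclass
class TruthTable:
    """Ground truth emitted alongside a simulated population."""

    founder_family: list[str]             # per founder: family letter
    founder_cnv_copies: list[int]         # per founder: CNV segment copies
    #: bird_id -> (sire-transmitted, dam-transmitted) haplotypes
    transmitted: dict[str, tuple[Haplotype, Haplotype]] = field(default_factory=dict)
    #: bird_id -> founder indices of the transmitted haplotypes (-1 = recombinant)
    transmitted_founders: dict[str, tuple[int, int]] = field(default_factory=dict)
    crossovers: list[CrossoverTruth] = field(default_factory=list)
    lei_mutations: list[LeiMutationTruth] = field(default_factory=list)


# ---------------------------------------------------------------------------
# panel
# ---------------------------------------------------------------------------

def default_panel(n_core: int = 90, n_flank: int = 11) -> SNPPanel:
    """A synthetic panel on the AB268588 coordinate system.

    Flank SNPs run 9,551–27,791 bp and include the six CNV-segment SNPs at
    12,062–13,992 bp; core SNPs are evenly spaced over 30,189–240,933 bp.
    Real inter-SNP spacing is uneven; even spacing is used because no
    per-SNP coordinate table is bundled.
    """
    snps: list[SNPDef] = []
    if n_flank > 0:
        cnv_lo, cnv_hi = CNV_SEGMENT_BP
        n_cnv = min(6, n_flank)
        cnv_pos = np.linspace(cnv_lo, cnv_hi, n_cnv).round().astype(int)
        other = [9_551, 17_607, 21_784, 24_800, 27_791][: n_flank - n_cnv]
        flank_pos = sorted(set(map(int, cnv_pos)) | set(other))
        for i, p in enumerate(flank_pos):
            gene = "BG2" if cnv_lo <= p <= cnv_hi else "KIFC1"
            snps.append(
                SNPDef(
                    name=f"MHCNew{i + 3:02d}",
                    position_bp=p,
                    allele_x="A",
                    allele_y="C",
                    gene=gene,
                    in_core=False,
                )
            )
    core_pos = np.linspace(30_189, 240_933, n_core).round().astype(int)
    for i, p in enumerate(core_pos):
        if i == 0 and n_core == 90:
            name = "MHCJ06"
        elif i == n_core - 1 and n_core == 90:
            name = "MHC178"
        else:
            name = f"MHCS{i + 1:03d}"
        snps.append(
            SNPDef(name=name, position_bp=int(p), allele_x="A", allele_y="G",
                   gene="", in_core=True)
        )
    return SNPPanel(snps=tuple(snps))


# ---------------------------------------------------------------------------
# founders
# ---------------------------------------------------------------------------

def _family_letters(n: int) -> list[str]:
    letters = []
    for i in range(n):
        q, r = divmod(i, 26)
        letters.append(string.ascii_uppercase[r] * (q + 1))
    return letters


def generate_founder_haplotypes(
    cfg: SimConfig, panel: SNPPanel | None = None
) -> tuple[list[Haplotype], TruthTable]:
    """Generate family-structured founder haplotypes with guaranteed
    Hamming separation.

    Family centroids are codewords of a binary code with a guaranteed
    minimum pairwise Hamming distance (the full complement for two
    families; rows of a Hadamard matrix, tiled over the core SNPs, for
    more), XORed onto a random base vector and column-permuted so per-SNP
    allele patterns look unstructured.  Within-family variants flip up to
    ``floor(within_family_diff/2)`` positions each, with disjoint flip
    sets.  This guarantees any within-family pair differs at <=
    ``within_family_diff`` core SNPs and any between-family pair at >=
    ``between_family_diff`` (feasibility is checked, not sampled for).
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_core_snps
    f = cfg.n_families
    k = cfg.haps_per_family
    if f < 1 or k < 1:
        raise ValueError("need at least one family and one haplotype per family")
    if cfg.between_family_diff > n:
        raise ValueError(
            f"between_family_diff={cfg.between_family_diff} infeasible on {n} SNPs"
        )
    t = cfg.within_family_diff // 2  # flips per non-centroid variant

    # family codewords with guaranteed minimum distance d_min
    if f == 1:
        code = np.zeros((1, n), dtype=np.int8)
        d_min = n
    elif f == 2:
        code = np.vstack([np.zeros(n, dtype=np.int8), np.ones(n, dtype=np.int8)])
        d_min = n
    else:
        from scipy.linalg import hadamard

        p = 4
        while p < f:
            p *= 2
        rows = (hadamard(p)[:f] == -1).astype(np.int8)
        code = np.tile(rows, (1, -(-n // p)))[:, :n]
        d_min = (n // p) * (p // 2)
    if f >= 2 and d_min - 2 * t < cfg.between_family_diff:
        raise ValueError(
            f"infeasible separation: {f} families on {n} SNPs guarantee only "
            f"{d_min - 2 * t} differences < between_family_diff="
            f"{cfg.between_family_diff}"
        )
    if k >= 2:
        if t < 1:
            raise ValueError(
                "haps_per_family >= 2 requires within_family_diff >= 2 "
                "(variants must differ somewhere)"
            )
        if (k - 1) * t > n:
            raise ValueError("too many within-family variants for the panel size")

    perm = rng.permutation(n)
    base = rng.integers(0, 2, size=n, dtype=np.int8)
    letters = _family_letters(f)
    if panel is None:
        panel = default_panel(n_core=n, n_flank=cfg.n_flank_snps)

    founders: list[Haplotype] = []
    families: list[str] = []
    lei_bases = [
        _LEI_PALETTE[i % len(_LEI_PALETTE)]
        for i in rng.permutation(len(_LEI_PALETTE))
    ]
    flip_pool = rng.permutation(n)
    for i in range(f):
        centroid = base ^ code[i][perm]
        lei = int(lei_bases[i % len(lei_bases)])
        for j in range(k):
            vec = centroid.copy()
            if j > 0:
                flips = flip_pool[(j - 1) * t: j * t]
                vec[flips] ^= 1
            founders.append(
                Haplotype(
                    alleles=tuple(Allele(int(v)) for v in vec),
                    lei_sizes=(lei,),
                )
            )
            families.append(letters[i])

    # CNV copy state and 5' flank alleles per founder
    if cfg.cnv_haplotype_profile is not None:
        copies = [cfg.cnv_haplotype_profile.get(i, 1) for i in range(len(founders))]
        if any(c not in (0, 1, 2) for c in copies):
            raise ValueError("cnv_haplotype_profile copies must be 0, 1 or 2")
    else:
        copies = [
            int(rng.choice([0, 1, 2], p=[0.19, 0.66, 0.15]))
            for _ in founders
        ]
    cnv_lo, cnv_hi = CNV_SEGMENT_BP
    flank = panel.flank_snps
    for idx, h in enumerate(founders):
        fl: list[Allele] = []
        for s in flank:
            in_cnv = cnv_lo <= s.position_bp <= cnv_hi
            if in_cnv and copies[idx] == 0:
                fl.append(Allele.MISSING)
            elif in_cnv and copies[idx] == 2:
                fl.append(Allele.BOTH)
            else:
                fl.append(Allele(int(rng.integers(0, 2))))
        founders[idx] = replace(h, flank5_alleles=tuple(fl))

    truth = TruthTable(founder_family=families, founder_cnv_copies=copies)
    return founders, truth


# ---------------------------------------------------------------------------
# population
# ---------------------------------------------------------------------------

def _combine_alleles(a1: Allele, a2: Allele) -> GenotypeCall:
    """Diploid call from two per-chromosome states (allele-content model:
    each chromosome contributes its allele content; a duplicated BOTH
    segment contributes one copy of each allele, a deleted segment none)."""
    contrib = {
        Allele.X: (1, 0), Allele.Y: (0, 1),
        Allele.BOTH: (1, 1), Allele.MISSING: (0, 0),
    }
    nx = contrib[a1][0] + contrib[a2][0]
    ny = contrib[a1][1] + contrib[a2][1]
    if nx == 0 and ny == 0:
        return GenotypeCall.FAIL
    if ny == 0:
        return GenotypeCall.XX
    if nx == 0:
        return GenotypeCall.YY
    if nx == 1 and ny == 1:
        return GenotypeCall.XY
    if nx == 2 and ny == 2:
        return GenotypeCall.AMBIG_BOTH
    if nx == 2 and ny == 1:
        return GenotypeCall.DUP_XXY
    return GenotypeCall.DUP_XYY


#: 4x4 lookup of _combine_alleles over integer allele codes
_CALL_TABLE = np.empty((4, 4), dtype=object)
for _a in Allele:
    for _b in Allele:
        _CALL_TABLE[int(_a), int(_b)] = _combine_alleles(_a, _b)


def _hap_codes(h: Haplotype, n_flank: int,
               _cache: dict = {}) -> np.ndarray:  # noqa: B006 - shared cache
    key = (h.key, h.flank5_alleles)
    arr = _cache.get(key)
    if arr is None:
        flank = h.flank5_alleles or (Allele.MISSING,) * n_flank
        arr = np.array([int(a) for a in flank] + [int(a) for a in h.alleles],
                       dtype=np.int8)
        if len(_cache) > 4096:
            _cache.clear()
        _cache[key] = arr
    return arr


def genotype_from_haplotypes(
    h1: Haplotype, h2: Haplotype, panel: SNPPanel
) -> list[GenotypeCall]:
    """The noise-free genotype row implied by a haplotype pair (all panel
    SNPs, flank first)."""
    n_flank = len(panel) - panel.n_core
    c1 = _hap_codes(h1, n_flank)
    c2 = _hap_codes(h2, n_flank)
    return list(_CALL_TABLE[c1, c2])


def _crossover(
    h5: Haplotype, h3: Haplotype, pos: int, panel: SNPPanel
) -> Haplotype:
    """Single-crossover product: h5 for panel positions <= pos, h3 after."""
    core_pos = panel.core_positions
    alleles = tuple(
        h5.alleles[i] if core_pos[i] <= pos else h3.alleles[i]
        for i in range(panel.n_core)
    )
    flank = None
    if h5.flank5_alleles is not None and h3.flank5_alleles is not None:
        fpos = [s.position_bp for s in panel.flank_snps]
        flank = tuple(
            h5.flank5_alleles[i] if fpos[i] <= pos else h3.flank5_alleles[i]
            for i in range(len(fpos))
        )
    lei = h5.lei_sizes if LEI_POSITION_BP <= pos else h3.lei_sizes
    return Haplotype(alleles=alleles, flank5_alleles=flank, lei_sizes=lei)


def _draw_position(rng: np.random.Generator,
                   bins: Sequence[tuple[int, int, float]]) -> int:
    w = np.array([b[2] for b in bins], dtype=float)
    i = int(rng.choice(len(bins), p=w / w.sum()))
    lo, hi, _ = bins[i]
    return int(rng.integers(lo, hi))


def simulate_population(
    founders: list[Haplotype],
    cfg: SimConfig,
    panel: SNPPanel | None = None,
    truth: TruthTable | None = None,
) -> tuple[GenotypeMatrix, TruthTable]:
    """Simulate a pedigreed multi-line cross and genotype every bird.

    Founder haplotypes are dealt to lines round-robin (``haps_per_line``
    each); every sire and dam carries two distinct haplotypes of its line
    where possible.  Each offspring receives one haplotype from its sire
    and one from its dam; with probability ``recomb_rate_per_offspring``
    one randomly chosen transmission is replaced by a single-crossover
    product at a position drawn from ``hotspot_bins``.
    """
    cfg.validate()
    if panel is None:
        panel = default_panel(n_core=cfg.n_core_snps, n_flank=cfg.n_flank_snps)
    if truth is None:
        truth = TruthTable(
            founder_family=["?"] * len(founders),
            founder_cnv_copies=[1] * len(founders),
        )
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 1]))
    if not founders:
        raise ValueError("no founder haplotypes")

    # deal founders to lines
    line_haps: list[list[int]] = [[] for _ in range(cfg.n_lines)]
    fi = 0
    for li in range(cfg.n_lines):
        for _ in range(cfg.haps_per_line):
            line_haps[li].append(fi % len(founders))
            fi += 1
    for li, hs in enumerate(line_haps):
        if not hs:
            raise ValueError(f"no founders assigned to line {li}")

    def parent_pair(line: int) -> tuple[int, int]:
        hs = line_haps[line]
        if len(set(hs)) >= 2:
            a, b = rng.choice(sorted(set(hs)), size=2, replace=False)
            return int(a), int(b)
        return hs[0], hs[0]

    bird_ids: list[str] = []
    line_ids: list[str] = []
    rows: list[list[GenotypeCall]] = []
    lei: dict[str, tuple[int, int]] = {}
    ped: dict[str, tuple[str, str]] = {}

    def line_of(i: int) -> str:
        return f"L{(i % cfg.n_lines) + 1}"

    sires: list[tuple[str, int, tuple[int, int]]] = []
    dams: list[tuple[str, int, tuple[int, int]]] = []
    for s in range(cfg.n_sires):
        li = s % cfg.n_lines
        sires.append((f"S{s + 1:03d}", li, parent_pair(li)))
    for d in range(cfg.n_dams):
        li = d % cfg.n_lines
        dams.append((f"D{d + 1:03d}", li, parent_pair(li)))

    def emit_bird(bid: str, line: str, h1: Haplotype, h2: Haplotype) -> None:
        bird_ids.append(bid)
        line_ids.append(line)
        rows.append(genotype_from_haplotypes(h1, h2, panel))
        la = h1.lei_sizes[0] if h1.lei_sizes else 0
        lb = h2.lei_sizes[0] if h2.lei_sizes else 0
        if la and lb:
            lei[bid] = (la, lb)

    for bid, li, (a, b) in sires + dams:
        emit_bird(bid, f"L{li + 1}", founders[a], founders[b])

    # offspring: dams dealt to sires evenly within their line
    recomb_flags = rng.random(cfg.n_offspring) < cfg.recomb_rate_per_offspring
    lei_flags = rng.random(cfg.n_offspring) < cfg.lei_mutation_rate
    for o in range(cfg.n_offspring):
        dam_id, dli, dpair = dams[o % len(dams)]
        same_line_sires = [s for s in sires if s[1] == dli] or sires
        sire_id, sli, spair = same_line_sires[
            (o // len(dams)) % len(same_line_sires)
        ]
        bid = f"O{o + 1:04d}"

        transmitted: list[Haplotype] = []
        founder_idx: list[int] = []
        which_rec = rng.integers(0, 2) if recomb_flags[o] else -1
        for role_i, (role, pair) in enumerate(
            (("sire", spair), ("dam", dpair))
        ):
            g1, g2 = pair
            if role_i == which_rec and g1 != g2:
                if rng.integers(0, 2):
                    g1, g2 = g2, g1
                pos = _draw_position(rng, cfg.hotspot_bins)
                hap = _crossover(founders[g1], founders[g2], pos, panel)
                truth.crossovers.append(
                    CrossoverTruth(
                        offspring_id=bid, parent_role=role,
                        position_bp=pos, founder_5prime=g1, founder_3prime=g2,
                    )
                )
                transmitted.append(hap)
                founder_idx.append(-1)
            else:
                g = g1 if rng.integers(0, 2) else g2
                transmitted.append(founders[g])
                founder_idx.append(g)

        # LEI0258 stepwise mutation on one randomly chosen transmission
        if lei_flags[o]:
            role_i = int(rng.integers(0, 2))
            h = transmitted[role_i]
            if h.lei_sizes:
                old = h.lei_sizes[0]
                step = int(rng.choice(cfg.lei_step_sizes))
                up = rng.random() < cfg.lei_up_bias
                new = old + step if up else old - step
                transmitted[role_i] = replace(h, lei_sizes=(new,))
                truth.lei_mutations.append(
                    LeiMutationTruth(
                        offspring_id=bid,
                        parent_role="sire" if role_i == 0 else "dam",
                        parental_size=old, new_size=new,
                    )
                )

        truth.transmitted[bid] = (transmitted[0], transmitted[1])
        truth.transmitted_founders[bid] = (founder_idx[0], founder_idx[1])
        ped[bid] = (sire_id, dam_id)
        emit_bird(bid, f"L{dli + 1}", transmitted[0], transmitted[1])

    calls = np.empty((len(bird_ids), len(panel)), dtype=object)
    for i, row in enumerate(rows):
        calls[i, :] = row
    m = GenotypeMatrix(
        panel=panel, bird_ids=bird_ids, line_ids=line_ids,
        calls=calls, lei0258=lei, pedigree=ped,
    )
    return m, truth


# ---------------------------------------------------------------------------
# assay channels
# ---------------------------------------------------------------------------

def simulate_kasp_fluorescence(
    call: GenotypeCall,
    noise_sd: float = 0.0,
    rng: np.random.Generator | None = None,
) -> tuple[float, float]:
    """Endpoint-fluorescence (vic, fam) for one call: the noiseless cluster
    centroid plus Gaussian noise truncated at 0.

    Intensities are normalized so that informative centroids sum to 1; the
    cluster geometry (signal ratios) is what carries the genotype.
    """
    vic, fam = KASP_CENTROIDS[call]
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        vic = max(0.0, vic + rng.normal(0.0, noise_sd))
        fam = max(0.0, fam + rng.normal(0.0, noise_sd))
    return float(vic), float(fam)


def simulate_qpcr(
    copies_per_diploid: int,
    efficiency: float = 2.0,
    noise_sd: float = 0.0,
    n_replicates: int = 6,
    rng: np.random.Generator | None = None,
    base_cq: float = 25.0,
) -> tuple[list[float], list[float]]:
    """Replicate Cq values (target, single-copy control) for a sample with
    ``copies_per_diploid`` copies of the CNV segment.

    E[Cq_target - Cq_control] = -log_eff(copies/2); zero copies give no
    target amplification (empty replicate list).
    """
    if not (1.0 < efficiency <= 2.0):
        raise ValueError("efficiency must be in (1, 2]")
    if copies_per_diploid < 0 or copies_per_diploid > 4:
        raise ValueError("copies_per_diploid must be in 0..4")
    if rng is None:
        rng = np.random.default_rng()
    control = [
        base_cq + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        for _ in range(n_replicates)
    ]
    if copies_per_diploid == 0:
        return [], control
    shift = -np.log(copies_per_diploid / 2.0) / np.log(efficiency)
    target = [
        base_cq + shift + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
        for _ in range(n_replicates)
    ]
    return target, control
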