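"""Haplotype inference by homozygote seeding and pattern subtraction.

The procedure mirrors how SNP haplotypes are defined from line-structured
genotyping data.  Within each line in which the MHC-B is segregating:

1. birds homozygous across the core SNPs (no heterozygous call) directly
   define haplotypes;
2. each heterozygous bird is compared against the known haplotypes; when
   exactly one known haplotype is compatible with its genotype, that
   pattern is subtracted and the remaining pattern defines a new
   haplotype;
3. rounds repeat until a fixpoint, and independently-defined haplotypes
   are then reconciled across lines.

Birds whose genotypes cannot be explained are reported as unresolved —
an expected outcome, not an error (e.g. two haplotypes that only ever
occur together in heterozygotes are not identifiable).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

from .panel import Allele, GenotypeCall, GenotypeMatrix, Haplotype

__all__ = [
    "HaplotypeSet",
    "LineInference",
    "SubtractionError",
    "haplotypes_from_homozygotes",
    "subtract_phase",
    "infer_line_haplotypes",
    "reconcile_across_lines",
    "name_haplotype",
    "assign_haplotype_names",
]


class SubtractionError(ValueError):
    """A known haplotype is incompatible with the genotype it is
    subtracted from."""


#: calls with at least one heterozygous chromosome pair (bird not
#: homozygous for the MHC)
_HET_CALLS = frozenset(
    {GenotypeCall.XY, GenotypeCall.DUP_XXY, GenotypeCall.DUP_XYY}
)

#: genotype call -> allele states compatible with one chromosome of it
_COMPATIBLE: dict[GenotypeCall, frozenset] = {
    GenotypeCall.XX: frozenset({Allele.X}),
    GenotypeCall.YY: frozenset({Allele.Y}),
    GenotypeCall.XY: frozenset({Allele.X, Allele.Y}),
    GenotypeCall.AMBIG_BOTH: frozenset({Allele.X, Allele.Y, Allele.BOTH}),
    GenotypeCall.DUP_XXY: frozenset({Allele.X, Allele.BOTH}),
    GenotypeCall.DUP_XYY: frozenset({Allele.Y, Allele.BOTH}),
    GenotypeCall.FAIL: frozenset(
        {Allele.X, Allele.Y, Allele.BOTH, Allele.MISSING}
    ),
    GenotypeCall.UNDEFINED: frozenset(
        {Allele.X, Allele.Y, Allele.BOTH, Allele.MISSING}
    ),
}


@dataclass
class HaplotypeSet:
    """Distinct haplotypes with observation counts and provenance."""

    haplotypes: list[Haplotype] = field(default_factory=list)
    #: per haplotype: set of (line_id, bird_id) supporting observations
    provenance: list[set[tuple[str, str]]] = field(default_factory=list)
    counts: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.haplotypes)

    def add(
        self,
        hap: Haplotype,
        prov: set[tuple[str, str]],
        count: int = 1,
    ) -> int:
        """Add an observation, collapsing exact duplicates (over the core
        vector); returns the haplotype's index."""
        key = hap.key
        for i, h in enumerate(self.haplotypes):
            if h.key == key:
                self.provenance[i] |= prov
                self.counts[i] += count
                return i
        self.haplotypes.append(hap)
        self.provenance.append(set(prov))
        self.counts.append(count)
        return len(self.haplotypes) - 1

    def index_of(self, hap: Haplotype) -> int | None:
        for i, h in enumerate(self.haplotypes):
            if h.key == hap.key:
                return i
        return None


@dataclass
class LineInference:
    """Outcome of iterative inference within one line."""

    haplotypes: HaplotypeSet
    #: bird_id -> (hap index, hap index) where a definite pair was derived
    assignments: dict[str, tuple[int, int]]
    #: birds explained by >=2 known haplotypes (pair ambiguous, no new
    #: haplotype derivable)
    ambiguous: list[str]
    unresolved: list[str]


def _is_homozygous(core_calls: list[GenotypeCall]) -> bool:
    return not any(c in _HET_CALLS for c in core_calls)


def _homozygote_allele(c: GenotypeCall) -> Allele:
    if c == GenotypeCall.XX:
        return Allele.X
    if c == GenotypeCall.YY:
        return Allele.Y
    if c == GenotypeCall.AMBIG_BOTH:
        return Allele.BOTH
    return Allele.MISSING  # FAIL / UNDEFINED


def haplotypes_from_homozygotes(m: GenotypeMatrix, line: str) -> HaplotypeSet:
    """Step 1: haplotypes defined directly by MHC-homozygous birds.

    A bird is homozygous iff no core SNP call is heterozygous; its
    haplotype takes the called allele per SNP (dual-allele calls give the
    BOTH state, fails give MISSING).  Duplicates collapse with counts.
    """
    if line not in m.lines:
        raise KeyError(f"line {line!r} not present")
    out = HaplotypeSet()
    for i in m.birds_in_line(line):
        core = m.core_calls(i)
        if _is_homozygous(core):
            hap = Haplotype(alleles=tuple(_homozygote_allele(c) for c in core))
            out.add(hap, {(line, m.bird_ids[i])})
    return out


def subtract_phase(
    core_calls: list[GenotypeCall], known: Haplotype
) -> Haplotype:
    """Subtract a known haplotype's pattern from a genotype vector,
    yielding the other chromosome's haplotype.

    Raises :class:`SubtractionError` (naming the first offending SNP
    index) if the known haplotype is incompatible with the genotype.
    """
    if len(core_calls) != len(known):
        raise SubtractionError(
            f"genotype length {len(core_calls)} != haplotype length {len(known)}"
        )
    out: list[Allele] = []
    for i, (g, a) in enumerate(zip(core_calls, known.alleles)):
        if a != Allele.MISSING and a not in _COMPATIBLE[g]:
            raise SubtractionError(
                f"known allele {a.name} incompatible with call {g.name} "
                f"at core SNP index {i}"
            )
        if g in (GenotypeCall.FAIL, GenotypeCall.UNDEFINED):
            out.append(Allele.MISSING)
        elif g == GenotypeCall.AMBIG_BOTH:
            out.append(Allele.BOTH)
        elif g == GenotypeCall.XX:
            out.append(Allele.X)
        elif g == GenotypeCall.YY:
            out.append(Allele.Y)
        elif g == GenotypeCall.XY:
            if a == Allele.MISSING:
                out.append(Allele.MISSING)
            else:
                out.append(Allele.Y if a == Allele.X else Allele.X)
        elif g == GenotypeCall.DUP_XXY:
            out.append(Allele.BOTH if a == Allele.X else Allele.X)
        else:  # DUP_XYY
            out.append(Allele.BOTH if a == Allele.Y else Allele.Y)
    return Haplotype(alleles=tuple(out))


def _compatible_knowns(
    core_calls: list[GenotypeCall], known: HaplotypeSet
) -> list[int]:
    idx = []
    for i, h in enumerate(known.haplotypes):
        if all(
            a == Allele.MISSING or a in _COMPATIBLE[g]
            for g, a in zip(core_calls, h.alleles)
        ):
            idx.append(i)
    return idx


def infer_line_haplotypes(
    m: GenotypeMatrix, line: str, max_rounds: int | None = None
) -> LineInference:
    """Iterate homozygote seeding + single-match subtraction to a fixpoint.

    Per round, each unexplained heterozygote is checked against the
    haplotypes known at the start of the round: exactly one compatible
    known haplotype -> subtract and add the complement; two or more ->
    the bird is explained but contributes nothing new; none -> it waits
    for a later round.  ``max_rounds`` defaults to the number of birds in
    the line (a guaranteed fixpoint bound).
    """
    if line not in m.lines:
        raise KeyError(f"line {line!r} not present")
    bird_idx = m.birds_in_line(line)
    if max_rounds is None:
        max_rounds = len(bird_idx)

    known = HaplotypeSet()
    assignments: dict[str, tuple[int, int]] = {}
    ambiguous: list[str] = []
    het_birds: list[tuple[str, list[GenotypeCall]]] = []
    for i in bird_idx:
        core = m.core_calls(i)
        bid = m.bird_ids[i]
        if _is_homozygous(core):
            hap = Haplotype(alleles=tuple(_homozygote_allele(c) for c in core))
            j = known.add(hap, {(line, bid)})
            assignments[bid] = (j, j)
        else:
            het_birds.append((bid, core))

    pending = het_birds
    for _ in range(max_rounds):
        if not pending:
            break
        matches = [(bid, core, _compatible_knowns(core, known))
                   for bid, core in pending]
        progressed = False
        still: list[tuple[str, list[GenotypeCall]]] = []
        for bid, core, comp in matches:
            if len(comp) == 1:
                complement = subtract_phase(core, known.haplotypes[comp[0]])
                j = known.add(complement, {(line, bid)})
                assignments[bid] = (comp[0], j)
                known.provenance[comp[0]].add((line, bid))
                progressed = True
            elif len(comp) >= 2:
                ambiguous.append(bid)
                progressed = True
            else:
                still.append((bid, core))
        pending = still
        if not progressed:
            break
    return LineInference(
        haplotypes=known,
        assignments=assignments,
        ambiguous=ambiguous,
        unresolved=[bid for bid, _ in pending],
    )


def _mergeable(a: Haplotype, b: Haplotype) -> bool:
    """Identical wherever both are non-missing."""
    return all(
        x == y
        for x, y in zip(a.alleles, b.alleles)
        if x != Allele.MISSING and y != Allele.MISSING
    )


def _merge(a: Haplotype, b: Haplotype) -> Haplotype:
    alleles = tuple(
        y if x == Allele.MISSING else x for x, y in zip(a.alleles, b.alleles)
    )
    lei = tuple(sorted(set(a.lei_sizes) | set(b.lei_sizes)))
    sero = a.serology + tuple(s for s in b.serology if s not in a.serology)
    return replace(a, alleles=alleles, lei_sizes=lei, serology=sero)


def reconcile_across_lines(sets: list[HaplotypeSet]) -> HaplotypeSet:
    """Step 3: merge independently-defined haplotypes across lines.

    Haplotypes identical over mutually non-missing core positions merge
    (missing positions fill from the counterpart, provenance unions); any
    non-missing disagreement keeps them distinct.  When several existing
    haplotypes could absorb a vector, the earliest (processing order) is
    chosen — a deterministic convention for a case the underlying
    procedure leaves open.
    """
    out = HaplotypeSet()
    for s in sets:
        for hap, prov, count in zip(s.haplotypes, s.provenance, s.counts):
            target = None
            for i, h in enumerate(out.haplotypes):
                if _mergeable(h, hap):
                    target = i
                    break
            if target is None:
                out.haplotypes.append(replace(hap))
                out.provenance.append(set(prov))
                out.counts.append(count)
            else:
                out.haplotypes[target] = _merge(out.haplotypes[target], hap)
                out.provenance[target] |= prov
                out.counts[target] += count
    return out


def name_haplotype(
    h: Haplotype,
    family_letter: str,
    index: int,
    variant_suffix: str | None = None,
) -> str:
    """Render a BSNP haplotype name.

    "BSNP-" + family letter + two-digit index (+ optional variant letter
    for haplotypes distinguished only in the 5' region), followed, when
    any annotation exists, by "(LEI sizes[;serology])", e.g.
    ``BSNP-A09A(357,369;BQ)``.
    """
    if not (1 <= index <= 99):
        raise ValueError(f"haplotype index {index} out of range 1..99")
    if len(family_letter) < 1 or not family_letter.isalpha():
        raise ValueError(f"bad family letter {family_letter!r}")
    name = f"BSNP-{family_letter.upper()}{index:02d}"
    if variant_suffix:
        name += variant_suffix.upper()
    if h.lei_sizes or h.serology:
        ann = ",".join(str(x) for x in h.lei_sizes)
        if h.serology:
            ann += ";" + ",".join(h.serology)
        name += f"({ann})"
    return name


def assign_haplotype_names(
    hapset: HaplotypeSet, families: dict[tuple[int, ...], str]
) -> list[str]:
    """Assign two-digit indices within each family — by descending
    observation count, ties broken lexicographically by allele vector —
    and render names."""
    order: dict[str, list[int]] = {}
    for i, h in enumerate(hapset.haplotypes):
        letter = families.get(h.key, "?")
        order.setdefault(letter, []).append(i)
    names = [""] * len(hapset)
    for letter, idxs in order.items():
        idxs.sort(key=lambda i: (-hapset.counts[i], hapset.haplotypes[i].key))
        for rank, i in enumerate(idxs, start=1):
            h = hapset.haplotypes[i]
            hapset.haplotypes[i] = replace(h, family_letter=letter, index=rank)
            names[i] = name_haplotype(hapset.haplotypes[i], letter, rank)
    return names
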