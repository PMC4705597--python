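"""Data model and file formats for the MHC-B SNP typing panel.

All genomic positions are 1-based coordinates on the 231,382-bp MHC-B
reference interval of GenBank AB268588 (the segment between the *BG2* and
*CD1A1* genes).  The panel is an ordered list of biallelic SNPs; the
haplotype-defining ("core") SNPs form a contiguous suffix of that order —
the 5' SNPs are excluded from haplotype definition because the region they
interrogate is subject to per-haplotype duplication and deletion.

Files are plain UTF-8 TSV with a header row; lines starting with ``#`` are
ignored.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Allele",
    "FormatError",
    "GenotypeCall",
    "GenotypeMatrix",
    "Haplotype",
    "SNPDef",
    "SNPPanel",
    "read_panel",
    "read_genotypes",
    "write_genotypes",
    "read_haplotype_table",
    "write_haplotype_table",
]

_NUCS = frozenset("ACGT")

#: IUPAC two-allele ambiguity codes (unordered nucleotide pair -> letter).
IUPAC_BOTH: Mapping[frozenset, str] = {
    frozenset("AC"): "M",
    frozenset("AG"): "R",
    frozenset("AT"): "W",
    frozenset("CG"): "S",
    frozenset("CT"): "Y",
    frozenset("GT"): "K",
}
IUPAC_LETTERS = frozenset(IUPAC_BOTH.values())


class FormatError(ValueError):
    """Raised for malformed panel / genotype / haplotype files."""


class GenotypeCall(enum.Enum):
    """Diploid call at one SNP, including copy-number-aware states.

    ``DUP_XXY`` / ``DUP_XYY`` are the two extra endpoint-fluorescence
    clusters produced when one chromosome carries a duplicated segment with
    both alleles (three amplifiable targets in a diploid).  ``AMBIG_BOTH``
    records "both alleles present" where the copy configuration is not
    resolved (rendered as IUPAC K/M/R/Y in tables).  ``FAIL`` is a
    consistent no-amplification result (rendered ``-``), ``UNDEFINED`` a
    fluorescence point rejected by the caller.
    """

    XX = "XX"
    YY = "YY"
    XY = "XY"
    DUP_XXY = "DUP_XXY"
    DUP_XYY = "DUP_XYY"
    AMBIG_BOTH = "AMBIG_BOTH"
    FAIL = "FAIL"
    UNDEFINED = "UNDEFINED"


class Allele(enum.IntEnum):
    """Per-haplotype state at one core SNP."""

    X = 0
    Y = 1
    BOTH = 2      # dual-allele (duplicated) segment on this chromosome
    MISSING = 3   # consistent assay failure; rendered "F" in tables


@dataclass(frozen=True)
class SNPDef:
    name: str
    position_bp: int
    allele_x: str
    allele_y: str
    gene: str = ""
    in_core: bool = True

    def __post_init__(self) -> None:
        if self.allele_x not in _NUCS or self.allele_y not in _NUCS:
            raise FormatError(
                f"SNP {self.name}: alleles must be nucleotides, got "
                f"{self.allele_x!r}/{self.allele_y!r}"
            )
        if self.allele_x == self.allele_y:
            raise FormatError(f"SNP {self.name}: allele_x == allele_y")
        if self.position_bp < 1:
            raise FormatError(f"SNP {self.name}: position must be 1-based positive")

    @property
    def iupac_both(self) -> str:
        return IUPAC_BOTH[frozenset((self.allele_x, self.allele_y))]


@dataclass(frozen=True)
class SNPPanel:
    """Ordered SNP panel anchored to one reference coordinate system."""

    snps: tuple[SNPDef, ...]
    reference_name: str = "AB268588"
    #: last coordinate covered by the typed segment (the 231,382-bp
    #: interval from 9,551 to 240,933 bp of the reference)
    reference_length: int = 240_933

    def __post_init__(self) -> None:
        names = [s.name for s in self.snps]
        if len(set(names)) != len(names):
            dup = sorted({n for n in names if names.count(n) > 1})
            raise FormatError(f"duplicate SNP names in panel: {dup}")
        pos = [s.position_bp for s in self.snps]
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise FormatError("panel positions must be strictly increasing")
        core = [s.in_core for s in self.snps]
        first_core = core.index(True) if any(core) else len(core)
        if not all(core[first_core:]):
            raise FormatError("core SNPs must form a contiguous suffix of the panel")

    def __len__(self) -> int:
        return len(self.snps)

    @property
    def core_snps(self) -> tuple[SNPDef, ...]:
        return tuple(s for s in self.snps if s.in_core)

    @property
    def flank_snps(self) -> tuple[SNPDef, ...]:
        return tuple(s for s in self.snps if not s.in_core)

    @property
    def n_core(self) -> int:
        return sum(s.in_core for s in self.snps)

    @property
    def core_positions(self) -> np.ndarray:
        return np.array([s.position_bp for s in self.core_snps], dtype=np.int64)

    @property
    def span(self) -> tuple[int, int]:
        """(first, last) panel position in bp."""
        return self.snps[0].position_bp, self.snps[-1].position_bp

    def index_of(self, name: str) -> int:
        for i, s in enumerate(self.snps):
            if s.name == name:
                return i
        raise KeyError(name)


@dataclass(frozen=True)
class Haplotype:
    """One chromosome's allele vector over the panel's core SNPs.

    ``alleles`` has one :class:`Allele` per core SNP, in panel order.
    Naming components (family letter, two-digit index, LEI0258 allele
    sizes, serological labels) are optional annotations; ``flank5_alleles``
    optionally records the non-core 5' SNP states.
    """

    alleles: tuple[Allele, ...]
    family_letter: str | None = None
    index: int | None = None
    variant_suffix: str | None = None
    lei_sizes: tuple[int, ...] = ()
    serology: tuple[str, ...] = ()
    flank5_alleles: tuple[Allele, ...] | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "alleles", tuple(Allele(a) for a in self.alleles))
        if self.flank5_alleles is not None:
            object.__setattr__(
                self, "flank5_alleles", tuple(Allele(a) for a in self.flank5_alleles)
            )

    def __len__(self) -> int:
        return len(self.alleles)

    @property
    def key(self) -> tuple[int, ...]:
        """Hashable identity over core SNPs (names/annotations excluded)."""
        return tuple(int(a) for a in self.alleles)

    def with_name(self, **kw) -> "Haplotype":
        return replace(self, **kw)

    def render(self, panel: SNPPanel) -> list[str]:
        """Nucleotide rendering of the core vector (F for missing)."""
        return [_allele_to_cell(a, s) for a, s in zip(self.alleles, panel.core_snps)]


def _allele_to_cell(a: Allele, snp: SNPDef) -> str:
    if a == Allele.X:
        return snp.allele_x
    if a == Allele.Y:
        return snp.allele_y
    if a == Allele.BOTH:
        return snp.iupac_both
    return "F"


def _cell_to_allele(cell: str, snp: SNPDef) -> Allele:
    if cell == "F":
        return Allele.MISSING
    if cell == snp.allele_x:
        return Allele.X
    if cell == snp.allele_y:
        return Allele.Y
    if cell == snp.iupac_both:
        return Allele.BOTH
    raise FormatError(f"illegal haplotype cell {cell!r} at SNP {snp.name}")


@dataclass
class GenotypeMatrix:
    """Birds x panel-SNPs diploid calls with optional annotations."""

    panel: SNPPanel
    bird_ids: list[str]
    line_ids: list[str]
    calls: np.ndarray  # object array of GenotypeCall, shape (n_birds, n_snps)
    lei0258: dict[str, tuple[int, int]] = field(default_factory=dict)
    pedigree: dict[str, tuple[str, str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        n_birds = len(self.bird_ids)
        if len(self.line_ids) != n_birds:
            raise FormatError("line_ids length must match bird_ids")
        if self.calls.shape != (n_birds, len(self.panel)):
            raise FormatError(
                f"calls grid {self.calls.shape} does not match "
                f"{n_birds} birds x {len(self.panel)} SNPs"
            )
        for bird, (sire, dam) in self.pedigree.items():
            known = set(self.bird_ids)
            for p in (sire, dam):
                if p and p not in known:
                    raise FormatError(f"pedigree of {bird} references unknown bird {p}")

    @property
    def lines(self) -> list[str]:
        seen: dict[str, None] = {}
        for l in self.line_ids:
            seen.setdefault(l)
        return list(seen)

    def birds_in_line(self, line: str) -> list[int]:
        return [i for i, l in enumerate(self.line_ids) if l == line]

    def core_calls(self, bird_index: int) -> list[GenotypeCall]:
        offset = len(self.panel) - self.panel.n_core
        return list(self.calls[bird_index, offset:])


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------

_PANEL_COLUMNS = ["name", "position_bp", "gene", "allele_x", "allele_y", "in_core"]


def _read_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)


def read_panel(path) -> SNPPanel:
    """Read a SNP panel TSV (columns: name, position_bp, gene, allele_x,
    allele_y, in_core). Rows may be in any order; the panel is sorted by
    position."""
    df = _read_tsv(path)
    missing = [c for c in _PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"panel file missing columns: {missing}")
    snps = []
    for _, row in df.iterrows():
        try:
            pos = int(row["position_bp"])
        except ValueError as e:
            raise FormatError(f"bad position {row['position_bp']!r}") from e
        snps.append(
            SNPDef(
                name=row["name"],
                position_bp=pos,
                gene=row["gene"],
                allele_x=row["allele_x"],
                allele_y=row["allele_y"],
                in_core=str(row["in_core"]).strip().lower() in ("1", "true", "yes"),
            )
        )
    snps.sort(key=lambda s: s.position_bp)
    return SNPPanel(snps=tuple(snps))


def write_panel(panel: SNPPanel, path) -> None:
    df = pd.DataFrame(
        {
            "name": [s.name for s in panel.snps],
            "position_bp": [s.position_bp for s in panel.snps],
            "gene": [s.gene for s in panel.snps],
            "allele_x": [s.allele_x for s in panel.snps],
            "allele_y": [s.allele_y for s in panel.snps],
            "in_core": [int(s.in_core) for s in panel.snps],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def _parse_genotype_cell(cell: str, snp: SNPDef) -> GenotypeCall:
    cell = cell.strip()
    if cell == "-":
        return GenotypeCall.FAIL
    if cell == "DUP:XXY":
        return GenotypeCall.DUP_XXY
    if cell == "DUP:XYY":
        return GenotypeCall.DUP_XYY
    if len(cell) == 1 and cell in IUPAC_LETTERS:
        if cell != snp.iupac_both:
            raise FormatError(
                f"IUPAC code {cell!r} does not match alleles "
                f"{snp.allele_x}/{snp.allele_y} of SNP {snp.name}"
            )
        return GenotypeCall.AMBIG_BOTH
    if len(cell) == 2 and set(cell) <= _NUCS:
        ax, ay = snp.allele_x, snp.allele_y
        pair = frozenset(cell)
        if pair == frozenset((ax,)):
            return GenotypeCall.XX
        if pair == frozenset((ay,)):
            return GenotypeCall.YY
        if pair == frozenset((ax, ay)):
            return GenotypeCall.XY
        raise FormatError(
            f"nucleotides {cell!r} do not match alleles {ax}/{ay} of SNP {snp.name}"
        )
    raise FormatError(f"illegal genotype cell {cell!r} at SNP {snp.name}")


def _render_genotype_cell(call: GenotypeCall, snp: SNPDef) -> str:
    ax, ay = snp.allele_x, snp.allele_y
    if call == GenotypeCall.XX:
        return ax + ax
    if call == GenotypeCall.YY:
        return ay + ay
    if call == GenotypeCall.XY:
        return "".join(sorted((ax, ay)))
    if call == GenotypeCall.AMBIG_BOTH:
        return snp.iupac_both
    if call == GenotypeCall.DUP_XXY:
        return "DUP:XXY"
    if call == GenotypeCall.DUP_XYY:
        return "DUP:XYY"
    return "-"


def read_genotypes(path, panel: SNPPanel) -> GenotypeMatrix:
    """Read a bird x SNP genotype TSV against ``panel``.

    Required columns: ``bird_id``, ``line_id``, one column per panel SNP.
    Optional: ``lei0258_a``/``lei0258_b`` (allele sizes in bp, blank for
    unknown) and ``sire_id``/``dam_id`` (blank for founders).
    """
    df = _read_tsv(path)
    for col in ("bird_id", "line_id"):
        if col not in df.columns:
            raise FormatError(f"genotype file missing column {col!r}")
    known = {s.name for s in panel.snps} | {
        "bird_id", "line_id", "lei0258_a", "lei0258_b", "sire_id", "dam_id"
    }
    unknown = [c for c in df.columns if c not in known]
    if unknown:
        raise FormatError(f"unknown SNP columns in genotype file: {unknown}")
    missing = [s.name for s in panel.snps if s.name not in df.columns]
    if missing:
        raise FormatError(f"genotype file missing SNP columns: {missing}")

    bird_ids = df["bird_id"].tolist()
    calls = np.empty((len(df), len(panel)), dtype=object)
    for j, snp in enumerate(panel.snps):
        col = df[snp.name].tolist()
        for i, cell in enumerate(col):
            calls[i, j] = _parse_genotype_cell(cell, snp)

    lei: dict[str, tuple[int, int]] = {}
    if "lei0258_a" in df.columns and "lei0258_b" in df.columns:
        for bird, a, b in zip(bird_ids, df["lei0258_a"], df["lei0258_b"]):
            if a != "" and b != "":
                lei[bird] = (int(a), int(b))
    ped: dict[str, tuple[str, str]] = {}
    if "sire_id" in df.columns and "dam_id" in df.columns:
        for bird, s, d in zip(bird_ids, df["sire_id"], df["dam_id"]):
            if s != "" or d != "":
                ped[bird] = (s, d)
    return GenotypeMatrix(
        panel=panel,
        bird_ids=bird_ids,
        line_ids=df["line_id"].tolist(),
        calls=calls,
        lei0258=lei,
        pedigree=ped,
    )


def write_genotypes(m: GenotypeMatrix, path) -> None:
    data: dict[str, list] = {"bird_id": m.bird_ids, "line_id": m.line_ids}
    if m.lei0258:
        data["lei0258_a"] = [
            str(m.lei0258[b][0]) if b in m.lei0258 else "" for b in m.bird_ids
        ]
        data["lei0258_b"] = [
            str(m.lei0258[b][1]) if b in m.lei0258 else "" for b in m.bird_ids
        ]
    if m.pedigree:
        data["sire_id"] = [m.pedigree.get(b, ("", ""))[0] for b in m.bird_ids]
        data["dam_id"] = [m.pedigree.get(b, ("", ""))[1] for b in m.bird_ids]
    for j, snp in enumerate(m.panel.snps):
        data[snp.name] = [_render_genotype_cell(c, snp) for c in m.calls[:, j]]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def haplotype_name(h: Haplotype) -> str:
    """Render a haplotype's display name, or '' if unnamed."""
    if h.family_letter is None or h.index is None:
        return ""
    from .phasing import name_haplotype  # single naming implementation

    return name_haplotype(
        h, h.family_letter, h.index, variant_suffix=h.variant_suffix
    )


def write_haplotype_table(haps: Sequence[Haplotype], panel: SNPPanel, path) -> None:
    """Write haplotypes as rows x core-SNP columns (plus a name column).

    Missing alleles are written as ``F``; dual-allele states as the SNP's
    IUPAC letter. Round-trips bit-exactly through
    :func:`read_haplotype_table`.
    """
    n_core = panel.n_core
    for h in haps:
        if len(h) != n_core:
            raise FormatError(
                f"haplotype of length {len(h)} does not match {n_core} core SNPs"
            )
    cols: dict[str, list] = {
        "name": [haplotype_name(h) for h in haps],
        "lei_sizes": [",".join(map(str, h.lei_sizes)) for h in haps],
        "serology": [",".join(h.serology) for h in haps],
    }
    for j, snp in enumerate(panel.core_snps):
        cols[snp.name] = [_allele_to_cell(h.alleles[j], snp) for h in haps]
    pd.DataFrame(cols).to_csv(path, sep="\t", index=False)


_NAME_RE = __import__("re").compile(
    r"^BSNP-(?P<rec>Rec)?(?P<fam>[A-Z])?(?P<idx>\d{2})(?P<suffix>[A-Z])?"
)


def read_haplotype_table(path, panel: SNPPanel) -> list[Haplotype]:
    df = _read_tsv(path)
    core = panel.core_snps
    missing = [s.name for s in core if s.name not in df.columns]
    if missing:
        raise FormatError(f"haplotype table missing core SNP columns: {missing}")
    haps = []
    for _, row in df.iterrows():
        alleles = tuple(_cell_to_allele(row[s.name], s) for s in core)
        fam = idx = suffix = None
        name = row.get("name", "")
        m = _NAME_RE.match(name) if name else None
        if m and not m.group("rec") and m.group("fam"):
            fam = m.group("fam")
            idx = int(m.group("idx"))
            suffix = m.group("suffix")
        lei = tuple(
            int(x) for x in str(row.get("lei_sizes", "")).split(",") if x.strip()
        )
        sero = tuple(
            x for x in str(row.get("serology", "")).split(",") if x.strip()
        )
        haps.append(
            Haplotype(
                alleles=alleles,
                family_letter=fam,
                index=idx,
                variant_suffix=suffix,
                lei_sizes=lei,
                serology=sero,
            )
        )
    return haps
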