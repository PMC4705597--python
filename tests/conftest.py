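import numpy as np
import pytest

from bsnptyper.panel import Allele, Haplotype, SNPDef, SNPPanel


def hap(pattern: str) -> Haplotype:
    """Haplotype from a compact string: X/Y/B (both)/F (missing)."""
    table = {"X": Allele.X, "Y": Allele.Y, "B": Allele.BOTH, "F": Allele.MISSING}
    return Haplotype(alleles=tuple(table[c] for c in pattern.upper()))


@pytest.fixture
def small_panel() -> SNPPanel:
    """Six core SNPs at 10kb..60kb plus one 5' flank SNP."""
    snps = [
        SNPDef(name="FL1", position_bp=2_000, allele_x="A", allele_y="C",
               in_core=False),
    ] + [
        SNPDef(name=f"C{i + 1}", position_bp=10_000 * (i + 1),
               allele_x="A", allele_y="G")
        for i in range(6)
    ]
    return SNPPanel(snps=tuple(snps), reference_length=70_000)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20_160_107)
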