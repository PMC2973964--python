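import numpy as np
import pytest

from ccravat import GenotypePanel, Individual, Marker


def make_panel(geno_rows, phenotype, trait_mode="binary", chrom="1",
               bp_start=1000, bp_spacing=1000):
    """Build a GenotypePanel from explicit genotypes.

    geno_rows: one list per individual of (allele1, allele2) tuples.
    phenotype: list of floats (NaN = missing); binary uses 1/2 codes.
    """
    n = len(geno_rows)
    m = len(geno_rows[0]) if n else 0
    individuals = [
        Individual(ped_id=str(i + 1), indiv_id=str(i + 1),
                   father_id="0", mother_id="0", sex=1)
        for i in range(n)
    ]
    markers = [
        Marker(name=f"SNP{j + 1}", chrom=chrom, bp=bp_start + j * bp_spacing)
        for j in range(m)
    ]
    a1 = np.array([[g[0] for g in row] for row in geno_rows], dtype="U8")
    a2 = np.array([[g[1] for g in row] for row in geno_rows], dtype="U8")
    if n == 0:
        a1 = np.empty((0, m), dtype="U8")
        a2 = np.empty((0, m), dtype="U8")
    return GenotypePanel(
        individuals=individuals, markers=markers, a1=a1, a2=a2,
        phenotype=np.asarray(phenotype, dtype=float), trait_mode=trait_mode,
    )


@pytest.fixture
def panel_factory():
    return make_panel


# the three-marker pedigree illustration used across format tests
PED_TEXT = """\
1 1 0 0 1 1 A A A C T G
2 2 0 0 2 1 A G A A G G
3 3 0 0 2 2 G G C C T T
4 4 0 0 1 2 A G A C T G
"""

MAP3_TEXT = """\
1 SNP1 1111
1 SNP2 2111
1 SNP3 3111
1 SNP4 4111
"""

MAP4_TEXT = """\
1 SNP1 0 1111
1 SNP2 1 2111
1 SNP3 2 3111
1 SNP4 3 4111
"""

GENE_TEXT = """\
7293 TNFRSF4 1 1136569 1139375
51150 SDF4 1 1142151 1157274
126792 B3GALT6 1 1157508 1160281
"""


@pytest.fixture
def ped_file(tmp_path):
    p = tmp_path / "chr1.ped"
    p.write_text(PED_TEXT)
    return p


@pytest.fixture
def map3_file(tmp_path):
    p = tmp_path / "chr1.map"
    p.write_text(MAP3_TEXT)
    return p


@pytest.fixture
def map4_file(tmp_path):
    p = tmp_path / "chr1_4col.map"
    p.write_text(MAP4_TEXT)
    return p


@pytest.fixture
def gene_file(tmp_path):
    p = tmp_path / "genes.txt"
    p.write_text(GENE_TEXT)
    return p
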