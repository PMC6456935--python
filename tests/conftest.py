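import numpy as np
import pytest

from apexdiff.simulate import default_design, simulate_cohort
from apexdiff.table import OtuTable


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort, shared across tests (seed 1)."""
    return simulate_cohort(default_design(1))


@pytest.fixture
def small_table():
    """A hand-sized table: 4 features x 3 samples with lineages."""
    return OtuTable(
        feature_ids=["f1", "f2", "f3", "f4"],
        taxonomy=[
            ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
             "Streptococcaceae", "Streptococcus"),
            ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
             "Streptococcaceae", "Streptococcus"),
            ("Bacteria", "Firmicutes", "Bacilli", "Lactobacillales",
             "Streptococcaceae"),
            ("Bacteria", "Bacteroidetes"),
        ],
        sample_ids=["S1", "S2", "S3"],
        counts=np.array([[3, 0, 1], [4, 2, 0], [5, 1, 1], [0, 7, 2]]),
    )


# Clinical annotation of the 23 untreated AP teeth: lesion dimension string,
# the published large/small lesion-area classification, and the published
# 2-cluster community subtype.  Used to pin the lesion parser and the
# concordance arithmetic.
CLINICAL_ROWS = [
    ("T_D_None_B.24", "2×2 mm", "SSA", "B"),
    ("T_D_None_B.23", "2×2 mm", "SSA", "B"),
    ("T_D_None_A.3", "2×3 mm", "SSA", "A"),
    ("T_D_None_A.25", "3×2 mm", "SSA", "A"),
    ("T_D_None_B.2", "3×2 mm", "SSA", "B"),
    ("T_D_None_B.15", "3×2 mm", "SSA", "B"),
    ("T_D_None_B.1", "3×3 mm", "SSA", "B"),
    ("T_D_None_B.27", "3×3 mm", "SSA", "B"),
    ("T_D_None_B.30", "3×3 mm", "SSA", "B"),
    ("T_D_None_A.14", "4x3mm", "SSA", "A"),
    ("T_D_None_A.26", "3×4 mm", "SSA", "A"),
    ("T_D_None_B.7", "4×3 mm", "SSA", "B"),
    ("T_D_None_B.22", "4×4 mm", "SSA", "B"),
    ("T_D_None_B.21", "4×4 mm", "SSA", "B"),
    ("T_D_None_A.28", "6×3 mm", "LSA", "A"),
    ("T_D_None_A.9", "4×5 mm", "LSA", "A"),
    ("T_D_None_A.12", "6×4 mm", "LSA", "A"),
    ("T_D_None_A.8", "6×5 mm", "LSA", "A"),
    ("T_D_None_A.19", "5×6 mm", "LSA", "A"),
    ("T_D_None_A.29", "6×5 mm", "LSA", "A"),
    ("T_D_None_A.5", "8×5 mm", "LSA", "A"),
    ("T_D_None_A.Xy", "8×5 mm", "LSA", "A"),
    ("T_D_None_A.13", "6×7 mm", "LSA", "A"),
]


@pytest.fixture(scope="session")
def clinical_rows():
    return CLINICAL_ROWS
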