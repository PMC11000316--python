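import numpy as np
import pytest

from omicsvote.io import EnsemblePrediction, read_feature_table

# Worked-example input table: six patient records with clinical columns, a
# peptide column, both label spellings, and three missing gland-size cells.
TABLE3_CSV = """\
Id,Age,ProstateGlandSize,TotalPsa,FTratio,PsaFree,Disease,sema7a
id100,57,95.00,8.94,24.0,2.14,BPH,15300
id19,73,NaN,0.07,71.0,0.05,BPH,29200
id74,47,20.0,6.97,8.0,0.59,PCA,31800
id30,62,50.0,19.71,10.0,1.97,PCa,9230
id144,73,NaN,1.83,16.0,0.29,PCa,28300
id142,72,NaN,8.05,21.0,1.71,PCa,22800
"""

# Published 12-patient validation report: ensemble calls of both strategies
# against the diagnosed class; patients 91 and 141 are the two errors.
TABLE2_ROWS = [
    ("121", "BPH", 0, 0),
    ("133", "BPH", 0, 0),
    ("39", "BPH", 0, 0),
    ("68", "BPH", 0, 0),
    ("84", "BPH", 0, 0),
    ("91", "BPH", 1, 1),
    ("1", "PCa", 1, 1),
    ("125", "PCa", 1, 1),
    ("126", "PCa", 1, 1),
    ("141", "PCa", 0, 0),
    ("17", "PCa", 1, 1),
    ("87", "PCa", 1, 1),
]


@pytest.fixture
def table3_path(tmp_path):
    p = tmp_path / "table3.csv"
    p.write_text(TABLE3_CSV)
    return p


@pytest.fixture
def table3(table3_path):
    return read_feature_table(table3_path)


@pytest.fixture
def table2_preds():
    soft = np.array([r[2] for r in TABLE2_ROWS])
    hard = np.array([r[3] for r in TABLE2_ROWS])
    y = np.array([1 if r[1] == "PCa" else 0 for r in TABLE2_ROWS])
    return EnsemblePrediction(
        sample_ids=[r[0] for r in TABLE2_ROWS],
        y_true=y,
        hard_labels=hard,
        soft_labels=soft,
    )
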