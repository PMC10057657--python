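import numpy as np
import pandas as pd
import pytest

from mirtriage.io import ExpressionMatrix


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """3 features x 6 samples, two per group, simple round numbers."""
    values = pd.DataFrame(
        {
            "n1": [1.0, 5.0, 7.0],
            "n2": [1.0, 5.2, 7.1],
            "t1": [3.0, 5.1, 7.2],
            "t2": [3.0, 5.3, 6.9],
            "f1": [3.0, 5.0, 7.3],
            "f2": [3.0, 5.2, 7.0],
        },
        index=["hsa-miR-a", "hsa-miR-b", "hsa-miR-c"],
    )
    groups = {"n1": "N", "n2": "N", "t1": "T", "t2": "T", "f1": "F1", "f2": "F1"}
    return ExpressionMatrix(values, groups)


@pytest.fixture
def matrix_files(tmp_path):
    """A 3-feature x 4-sample expression TSV plus its sample sheet."""
    mat = tmp_path / "expr.tsv"
    mat.write_text(
        "feature_id\ts1\ts2\ts3\ts4\n"
        "hsa-miR-21-3p\t5.0\t5.1\t7.0\t7.2\n"
        "hsa-miR-509-5p\t6.0\t6.1\t5.0\t5.2\n"
        "mmu-miR-1\t4.0\t4.1\t4.0\t4.2\n"
    )
    sheet = tmp_path / "sheet.tsv"
    sheet.write_text("sample_id\tgroup\ns1\tN\ns2\tN\ns3\tT\ns4\tT\n")
    return mat, sheet


def de_frame(rows):
    """Helper: build a DE table from (feature_id, fold_change, p_value) rows."""
    return pd.DataFrame(rows, columns=["feature_id", "fold_change", "p_value"])
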