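import numpy as np
import pandas as pd
import pytest

from rankscore import ExpressionMatrix, GeneSignature


@pytest.fixture
def ladder_em() -> ExpressionMatrix:
    """10 genes, 1 sample, abundances 1..10 (gene gK has rank K)."""
    return ExpressionMatrix(
        pd.DataFrame({"s1": np.arange(1.0, 11.0)},
                     index=[f"g{i}" for i in range(1, 11)])
    )


@pytest.fixture
def random_em() -> ExpressionMatrix:
    rng = np.random.default_rng(42)
    data = pd.DataFrame(
        rng.lognormal(2.0, 1.0, size=(50, 8)),
        index=[f"g{i:03d}" for i in range(50)],
        columns=[f"s{j}" for j in range(8)],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def bidir_sig() -> GeneSignature:
    return GeneSignature(
        "emt", "bidirectional",
        frozenset({"g008", "g012", "g031"}),
        frozenset({"g002", "g040"}),
    )


@pytest.fixture
def tsv_writer(tmp_path):
    def _write(df: pd.DataFrame, name: str = "expr.tsv"):
        path = tmp_path / name
        df.to_csv(path, sep="\t", index_label="gene_id")
        return path
    return _write


@pytest.fixture
def gmt_writer(tmp_path):
    def _write(lines: list[str], name: str = "sets.gmt"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path
    return _write
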