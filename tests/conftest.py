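import numpy as np
import pandas as pd
import pytest

from coexrank import ExpressionMatrix, ModuleSpec, generate_expression, generate_supporting_files


@pytest.fixture
def toy_matrix() -> ExpressionMatrix:
    """4-gene matrix with a perfect correlate, a perfect anti-correlate and a
    tied pair (g4 correlates 0.8 with both g1 and g2)."""
    return ExpressionMatrix(
        pd.DataFrame(
            [[1, 2, 3, 4], [2, 4, 6, 8], [4, 3, 2, 1], [1, 3, 2, 4]],
            index=["g1", "g2", "g3", "g4"],
            columns=["s1", "s2", "s3", "s4"],
        )
    )


TWO_MODULES = [
    ModuleSpec("M1", 10, 0.9, "GO:2000001"),
    ModuleSpec("M2", 10, 0.9, "GO:2000002"),
]


@pytest.fixture(scope="session")
def planted() -> tuple:
    """300-gene, 30-sample matrix with two planted 10-gene modules."""
    matrix, truth = generate_expression(300, 30, TWO_MODULES, seed=20260923)
    return matrix, truth


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory, planted):
    """Planted dataset written to disk with its full supporting-file set."""
    matrix, truth = planted
    out = tmp_path_factory.mktemp("fixtures")
    matrix.write(out / "expression.tsv")
    truth.to_csv(out / "truth.tsv", sep="\t", index=False)
    paths = generate_supporting_files(truth, out, seed=20260923, modules=TWO_MODULES)
    paths["expression"] = out / "expression.tsv"
    paths["truth"] = out / "truth.tsv"
    return paths


def random_matrix(rng: np.random.Generator, n_genes: int, n_samples: int, with_ties: bool = True) -> ExpressionMatrix:
    """Random matrix; optionally plant bit-exact PCC ties by duplicating a
    row and rescaling another by a power of two (both exact in floats, so
    the tied correlations are identical in any correct implementation)."""
    values = rng.standard_normal((n_genes, n_samples))
    if with_ties and n_genes >= 4:
        values[1] = values[0]
        values[3] = 2.0 * values[2]
    genes = [f"g{i:03d}" for i in range(n_genes)]
    samples = [f"s{j:02d}" for j in range(n_samples)]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
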