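import numpy as np
import pandas as pd
import pytest

from g0kit import (
    DETable,
    ExpressionMatrix,
    GeneSignature,
    STRESS_PROGRAMMES,
    StressSignatureSet,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260927)


@pytest.fixture
def small_sig():
    return GeneSignature(name="toy", up=["U1", "U2", "U3"], down=["D1", "D2"])


@pytest.fixture
def seeded_matrix(rng):
    """10 genes x 6 samples, deterministic, includes the toy signature genes."""
    genes = ["U1", "U2", "U3", "D1", "D2", "N1", "N2", "N3", "N4", "N5"]
    samples = [f"s{i}" for i in range(6)]
    values = rng.normal(5.0, 2.0, size=(10, 6))
    return ExpressionMatrix(genes=genes, samples=samples, values=values)


def make_de_table(rows: dict[str, dict[str, float]]) -> DETable:
    """Build a DETable from {gene: {form: log2fc}}; padj defaults to 0.001
    unless given as (log2fc, padj) tuples."""
    records = {}
    for gene, per_form in rows.items():
        rec = {}
        for form in STRESS_PROGRAMMES:
            v = per_form[form]
            fc, padj = v if isinstance(v, tuple) else (v, 0.001)
            rec[f"log2fc_{form}"] = fc
            rec[f"padj_{form}"] = padj
        records[gene] = rec
    return DETable(frame=pd.DataFrame.from_dict(records, orient="index"))


@pytest.fixture
def disjoint_stress_sigs():
    """Five stress signatures over disjoint gene pools (10 up / 10 down each)."""
    programmes = {}
    for k, p in enumerate(STRESS_PROGRAMMES):
        up = [f"{p}_up{i}" for i in range(10)]
        down = [f"{p}_dn{i}" for i in range(10)]
        programmes[p] = GeneSignature(name=p, up=up, down=down)
    return StressSignatureSet(programmes=programmes)


@pytest.fixture
def shared_generic_sig():
    """Generic G0 signature on its own genes, elevated in every arrested
    cell regardless of the inducing stress programme."""
    return GeneSignature(
        name="generic",
        up=[f"gen_up{i}" for i in range(15)],
        down=[f"gen_dn{i}" for i in range(15)],
    )
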