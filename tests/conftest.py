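import numpy as np
import pandas as pd
import pytest

from episign.io import BetaMatrix, SampleSheet
from episign.simulate import CaseGroupSpec, SimulationParams, simulate_beta_matrix


@pytest.fixture(scope="session")
def small_hyper_cohort():
    """A compact planted-hypermethylation cohort shared across tests.

    24 controls vs 4 hyper cases (delta 0.30) on 6000 CpGs; small enough
    to fit in every unit test, large enough to carry planted islands.
    """
    params = SimulationParams(
        seed=7,
        n_cpg=6000,
        n_controls=24,
        n_islands=200,
        case_groups=(CaseGroupSpec("case_hyper", 4, "hyper", 0.30, n_islands=8, n_blocks=0),),
    )
    matrix, sheet, truth, annotation = simulate_beta_matrix(params)
    return {
        "params": params,
        "matrix": matrix,
        "sheet": sheet,
        "truth": truth,
        "annotation": annotation,
    }


@pytest.fixture(scope="session")
def null_control_matrix():
    """Pure-null controls: no case effect, mild covariates only."""
    params = SimulationParams(
        seed=11,
        n_cpg=4000,
        n_controls=30,
        n_islands=150,
        case_groups=(),
    )
    matrix, sheet, truth, annotation = simulate_beta_matrix(params)
    return {"matrix": matrix, "sheet": sheet, "annotation": annotation}


def make_beta_matrix(beta: np.ndarray, coverage: np.ndarray | None = None,
                     chrom: str = "chr1", start: int = 100, step: int = 100,
                     samples: list[str] | None = None) -> BetaMatrix:
    """Small hand-built BetaMatrix helper."""
    n_sites, n_samples = beta.shape
    samples = samples or [f"S{i + 1}" for i in range(n_samples)]
    idx = pd.MultiIndex.from_arrays(
        [[chrom] * n_sites, [start + i * step for i in range(n_sites)]],
        names=["chrom", "pos"],
    )
    if coverage is None:
        coverage = np.full_like(beta, 30.0, dtype=float)
        coverage[np.isnan(beta)] = np.nan
    return BetaMatrix(
        pd.DataFrame(beta, index=idx, columns=samples),
        pd.DataFrame(coverage, index=idx, columns=samples),
    )


def make_sheet(groups: dict[str, int], seed: int = 0) -> SampleSheet:
    rng = np.random.default_rng(seed)
    rows = []
    i = 0
    for group, n in groups.items():
        for _ in range(n):
            i += 1
            rows.append((f"S{i}", group, float(rng.integers(1, 60)),
                         "M" if rng.random() < 0.5 else "F",
                         "B1" if rng.random() < 0.5 else "B2", ""))
    return SampleSheet(pd.DataFrame(rows, columns=["id", "group", "age", "sex", "batch", "variant"]))
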