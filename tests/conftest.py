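import numpy as np
import pytest

from hervarch.segment import revcomp  # noqa: F401  (re-used by tests)


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


def mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = []
    for base in seq:
        if rng.random() < rate:
            out.append(rng.choice([b for b in "ACGT" if b != base]))
        else:
            out.append(base)
    return "".join(out)


@pytest.fixture(scope="session")
def small_consensi():
    """Desk-scale LTR/INT consensus pair for fast segmentation tests."""
    rng = np.random.default_rng(42)
    return {"LTR": random_dna(rng, 300), "INT": random_dna(rng, 800)}


@pytest.fixture(scope="session")
def default_cohort_dir(tmp_path_factory):
    """One default-condition cohort (n=60), simulated once per session."""
    from hervarch import SimConfig, simulate_cohort

    outdir = tmp_path_factory.mktemp("cohort")
    result = simulate_cohort(SimConfig(n_samples=60, seed=11), outdir=outdir)
    return outdir, result
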