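import numpy as np
import pandas as pd
import pytest

from triomr import InstrumentSet


def make_instruments(
    beta_exp, se_exp, beta_out, se_out, eaf=None, ids=None
) -> InstrumentSet:
    """Build a harmonized instrument set from raw arrays."""
    beta_exp = np.asarray(beta_exp, dtype=float)
    k = len(beta_exp)
    table = pd.DataFrame(
        {
            "variant_id": ids or [f"rs{i + 1}" for i in range(k)],
            "beta_exp": beta_exp,
            "se_exp": np.asarray(se_exp, dtype=float),
            "beta_out": np.asarray(beta_out, dtype=float),
            "se_out": np.asarray(se_out, dtype=float),
            "eaf_exp": np.full(k, 0.3) if eaf is None else np.asarray(eaf),
            "f_stat": (np.asarray(beta_exp) / np.asarray(se_exp)) ** 2,
            "flipped": False,
        }
    )
    return InstrumentSet(exposure_id="exp", outcome_id="out", table=table)


def random_instruments(rng: np.random.Generator, k: int = 20) -> InstrumentSet:
    """Random but well-behaved instrument set for oracle comparisons."""
    beta_exp = rng.uniform(0.05, 0.5, k) * rng.choice([-1, 1], k)
    se_exp = rng.uniform(0.005, 0.02, k)
    se_out = rng.uniform(0.01, 0.05, k)
    beta_out = 0.1 * beta_exp + rng.normal(0, se_out)
    return make_instruments(beta_exp, se_exp, beta_out, se_out)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
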