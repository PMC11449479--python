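import dataclasses

import numpy as np
import pandas as pd
import pytest

import lpptether as lp
from lpptether.synthetic import SyntheticConfig


@pytest.fixture(scope="session")
def table():
    """Exact (unrounded) 7x4 theoretical mass grid of the Tri->KR ladder."""
    return lp.theoretical_table()


@pytest.fixture(scope="session")
def library():
    return lp.residue_library()


@pytest.fixture(scope="session")
def wt_params():
    """Wild type: steady tethered fraction, half the bonds hydrolyzed per generation."""
    return lp.wild_type_params()


@pytest.fixture(scope="session")
def mut_params(wt_params):
    """dyafK mutant sharing the wild-type enzyme rate, with hydrolysis off."""
    return dataclasses.replace(wt_params, k_h=0.0)


def intensities_to_quant(intensities: pd.DataFrame) -> pd.DataFrame:
    """Per-row relative abundances (%) from an intensity table."""
    quant = intensities.copy()
    rel = quant[["nn", "oo", "on", "no"]].to_numpy()
    quant[["nn", "oo", "on", "no"]] = 100.0 * rel / rel.sum(axis=1, keepdims=True)
    return quant


@pytest.fixture(scope="session")
def synthetic_pair(wt_params, mut_params):
    """One noisy synthetic (wild type, mutant) quant-table pair at study conditions."""
    ints_wt, truth_wt = lp.generate_timecourse(
        SyntheticConfig(params=wt_params, seed=101, cv=0.10, n_replicates=5)
    )
    ints_mut, truth_mut = lp.generate_timecourse(
        SyntheticConfig(params=mut_params, seed=102, cv=0.10, n_replicates=5)
    )
    return {
        "wt": intensities_to_quant(ints_wt),
        "mut": intensities_to_quant(ints_mut),
        "truth_wt": truth_wt,
        "truth_mut": truth_mut,
    }
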