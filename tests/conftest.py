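import numpy as np
import pytest

from nitrisip import synthetic as syn
from nitrisip.sipquant import FractionProfile, GradientPair


@pytest.fixture(scope="session")
def ck_scenario():
    return syn.make_scenario("CK", seed=7)


@pytest.fixture(scope="session")
def wi2_scenario():
    return syn.make_scenario("WI2", seed=7)


def single_gene_truth(p_true: float, gc: float = 0.5, atom_excess: float = 1.0,
                      total: float = 1e7) -> syn.LabelTruth:
    return syn.LabelTruth(
        genes={"gene": syn.GeneLabelTruth(gc, atom_excess, p_true, total)}
    )


def pair_from_window_sums(s12: float, s13: float, n_rep: int = 3) -> GradientPair:
    """3-fraction pair whose heavy window {1} has exact relative-abundance
    sums s12/s13 in every replicate."""

    def prof(iso, share, rep):
        return FractionProfile(
            gene="g", isotope=iso, replicate=f"r{rep}",
            indices=(1, 2, 3), densities=(1.74, 1.72, 1.70),
            copies=(share * 100.0, (1 - share) * 60.0, (1 - share) * 40.0),
        )

    return GradientPair(
        gene="g",
        profiles_12C=tuple(prof("12C", s12, r) for r in range(n_rep)),
        profiles_13C=tuple(prof("13C", s13, r) for r in range(n_rep)),
        analysis_range=(1, 3),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
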