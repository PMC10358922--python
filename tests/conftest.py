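import numpy as np
import pytest

from screenvar import (
    ELIGIBILITY_SCHEDULE,
    SyntheticConfig,
    compute_spr,
    default_national_rates,
    expected_counts,
    make_lattice,
    national_age_rates,
    sample_leroux_field,
    simulate_counts,
    true_parameters,
)


@pytest.fixture(scope="session")
def small_system():
    """A 10x10 synthetic screening system with known ground truth."""
    cfg = SyntheticConfig(n_rows=10, n_cols=10, seed=11, mean_pop=2000.0)
    areas, adj = make_lattice(cfg)
    rng = np.random.default_rng(11)
    psi = sample_leroux_field(adj, cfg.rho, cfg.tau2, rng=rng)
    truth = true_parameters(areas, psi, cfg)
    rates_in = default_national_rates()
    counts = simulate_counts(areas, ELIGIBILITY_SCHEDULE, rates_in, truth, rng=rng)
    rates = national_age_rates(counts)
    expected = expected_counts(areas, ELIGIBILITY_SCHEDULE, rates, "2019-2020")
    spr = compute_spr(counts, expected)
    return {
        "config": cfg, "areas": areas, "adj": adj, "truth": truth,
        "rates_in": rates_in, "counts": counts, "rates": rates,
        "expected": expected, "spr": spr,
    }


@pytest.fixture(scope="session")
def null_system():
    """A flat system: theta identically one, no covariate effects."""
    cfg = SyntheticConfig(n_rows=8, n_cols=8, seed=5, mean_pop=4000.0,
                          covariate_effects={}, beta0=0.0, tau2=0.25)
    areas, adj = make_lattice(cfg)
    from screenvar.synthetic import TrueParameters
    n = len(areas)
    truth = TrueParameters(psi=np.zeros(n), theta=np.ones(n))
    rates_in = default_national_rates()
    counts = simulate_counts(areas, ELIGIBILITY_SCHEDULE, rates_in, truth, seed=6)
    rates = national_age_rates(counts)
    expected = expected_counts(areas, ELIGIBILITY_SCHEDULE, rates, "2019-2020")
    return {"config": cfg, "areas": areas, "adj": adj, "truth": truth,
            "counts": counts, "rates": rates, "expected": expected}
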