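import time

import pytest

from wes_reanalysis import cohort_sim, pipeline


@pytest.fixture(scope="session")
def default_run():
    """Default study-condition cohort (10 trios x 20k sites, depth 40,
    error 0.005) with one planted event per class, plus the timed
    end-to-end pipeline result over it."""
    t0 = time.perf_counter()
    cohort = cohort_sim.simulate_cohort(cohort_sim.default_cohort_config(seed=1729))
    result = pipeline.run_pipeline(cohort.site_calls, cohort.pedigree, cohort.exon_coverage)
    elapsed = time.perf_counter() - t0
    return {"cohort": cohort, "result": result, "elapsed": elapsed}


@pytest.fixture(scope="session")
def small_cohort():
    """Seven-family miniature of the default conditions for unit tests."""
    cfg = cohort_sim.default_cohort_config(seed=42, n_families=7, n_background_sites=4000)
    return cohort_sim.simulate_cohort(cfg)
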