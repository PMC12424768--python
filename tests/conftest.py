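import pytest

from mecgamma.experiments import simulate_condition


@pytest.fixture(scope="session")
def run_cond():
    """Memoized desk-scale network condition runner shared across tests.

    Keyed on (g_ei, seed, blocked, e_gaba_ii, n_cycles); many acceptance
    checks share conditions (e.g. the E->I = 0 run is the same network for
    every control conductance), so caching keeps the suite fast.
    """
    cache = {}

    def run(g_ei, seed, blocked=False, e_gaba_ii=-75.0, n_cycles=11):
        eg = e_gaba_ii if not isinstance(e_gaba_ii, str) else e_gaba_ii
        key = (0.0 if blocked else float(g_ei), seed, blocked, eg, n_cycles)
        if key not in cache:
            cache[key] = simulate_condition(
                g_ei, seed, block_ei=blocked, e_gaba_ii=e_gaba_ii,
                n_cycles=n_cycles)
        return cache[key]

    return run
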