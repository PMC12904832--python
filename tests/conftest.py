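import pytest

import reprored as rr

# Pinned witness of baseline non-reproducibility: a cancellation-regime array
# on which the conventional per-PE reduction yields several distinct bit
# patterns across PE counts (found by evaluation, then frozen).
WITNESS = {"regime": "cancellation", "n": 64, "seed": 0}


@pytest.fixture(scope="session")
def fadd():
    return rr.make_operator("float-add")


@pytest.fixture(scope="session")
def concat():
    return rr.make_operator("concat")


def run_repro_reduce(values, p, degree, scheme, seed, op):
    """Compile + execute one reproducible reduction configuration."""
    n = len(values)
    own = rr.gen_ownership(n, p, scheme, seed)
    sched = rr.compile_schedule(
        rr.build_reduction_tree(n), rr.build_comm_tree(p, degree), own
    )
    return rr.execute_reduce(sched, values, op)
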