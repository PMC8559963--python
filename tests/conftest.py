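import numpy as np
import pytest

from nlrkit.fixtures import FixtureSpec, MotifPlan


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def spec_pool() -> list[FixtureSpec]:
    """Fixture blueprints spanning all 7 categories and >= 12 architectures."""
    return [
        # NLR, varied architectures
        FixtureSpec("CNL"),
        FixtureSpec("TNL"),
        FixtureSpec("RNL"),
        FixtureSpec("1CNL"),
        FixtureSpec("CONL"),
        FixtureSpec("TNLJ"),
        FixtureSpec("N"),
        FixtureSpec("NL"),
        FixtureSpec("CN"),
        FixtureSpec("TNNL"),
        FixtureSpec("CNLO"),
        FixtureSpec("N", nbarc_mode="motif"),           # motif-anchored NB-ARC
        # degenerate
        FixtureSpec("C", motif_plan=(), extra_domains=("ploop",)),
        FixtureSpec("T", motif_plan=(), extra_domains=("ploop",)),
        FixtureSpec("L", motif_plan=(MotifPlan(7, 90.0),)),
        FixtureSpec("CL", motif_plan=(MotifPlan(2, 65.0),)),
        # TX / CCX / RPW8 / MLKL / non-NLR
        FixtureSpec("T", motif_plan=()),
        FixtureSpec("TL", motif_plan=()),
        FixtureSpec("C", motif_plan=()),
        FixtureSpec("1L", motif_plan=()),
        FixtureSpec("R", motif_plan=()),
        FixtureSpec("", motif_plan=(), extra_domains=("helo",)),
        FixtureSpec("L", motif_plan=()),
        FixtureSpec("O", motif_plan=()),
    ]


def replicate_pool(n: int) -> list[FixtureSpec]:
    pool = spec_pool()
    return [pool[i % len(pool)] for i in range(n)]
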