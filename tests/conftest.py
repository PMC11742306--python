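import numpy as np
import pytest

from tilescope.pyramid import SlidePyramid, ViewState
from tilescope.scheduler import Engine, EngineConfig
from tilescope.synthetic import TracePoint, ViewTrace, generate_slide


@pytest.fixture(scope="session")
def smooth_store(tmp_path_factory):
    """Smooth nucleus-free 1024x1024 slide shared by compositor tests."""
    root = tmp_path_factory.mktemp("smooth_slide")
    return generate_slide(root, 1024, 1024, 0, seed=3, factors=[1, 2, 4])


@pytest.fixture(scope="session")
def big_pyramid():
    """Virtual 16k pyramid for scheduler simulations (no pixel store needed)."""
    return SlidePyramid.power_of_two(16384, 16384)


def stationary_engine(store, view: ViewState, alpha: float = 0.0, until: float = 3000.0) -> Engine:
    """Run the engine on a single fixed view until the field is fully buffered."""
    cfg = EngineConfig(
        compute_mipmaps=True,
        mipmap_alpha=alpha,
        loader_jitter_mean_ms=0.0,
        pool_size=256,
    )
    eng = Engine(store.pyramid, cfg, store=store)
    eng.run(ViewTrace([TracePoint(0.0, view, False)]), until=until)
    return eng


def rng_views(rng: np.random.Generator, pyramid: SlidePyramid) -> ViewState:
    """Random view roughly over the slide (may spill past the edges)."""
    return ViewState(
        screen_width=int(rng.integers(64, 1200)),
        screen_height=int(rng.integers(64, 900)),
        zoom=float(2.0 ** rng.uniform(-3.5, 1.5)),
        center_x=float(rng.uniform(-0.1, 1.1) * pyramid.base_width),
        center_y=float(rng.uniform(-0.1, 1.1) * pyramid.base_height),
    )
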