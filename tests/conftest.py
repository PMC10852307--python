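import numpy as np
import pytest

from plelscape.plel_core import CategoricalRaster, NAME_TO_CODE
from plelscape import synthetic_data as sd


@pytest.fixture(scope="session")
def toy_unit_raster() -> CategoricalRaster:
    """One 3 km x 3 km unit at 100 m cells (900 cells = 900 hm2):
    GEL 600 hm2 in exactly 2 patches, APL 300 hm2 in exactly 3 patches.

    An APL band (rows 14-17, 120 cells) splits the grassland into two
    patches; two isolated APL blocks (90 cells each) sit inside them.
    """
    gel, apl = NAME_TO_CODE["GEL"], NAME_TO_CODE["APL"]
    v = np.full((30, 30), gel, dtype=int)
    v[14:18, :] = apl
    v[2:11, 2:12] = apl
    v[20:29, 15:25] = apl
    return CategoricalRaster(values=v, cell_size=100.0)


@pytest.fixture(scope="session")
def small_synth_series():
    """120x120 three-epoch synthetic series with lake and drivers (seeded)."""
    cfg = sd.SyntheticConfig(seed=11, width=120, height=120, n_epochs=3)
    lake = sd.restricted_disc(cfg)
    base = sd.stamp_lake(sd.generate_landscape(cfg), lake)
    series = sd.evolve_series(base, cfg, restricted=lake)
    drivers = sd.generate_drivers(cfg)
    return {"config": cfg, "lake": lake, "series": series, "drivers": drivers}
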