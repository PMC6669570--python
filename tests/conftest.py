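import logging

import pytest

from portalcontrast import fixtures as fx


@pytest.fixture(scope="session", autouse=True)
def _quiet_logs():
    logging.getLogger("portalcontrast").setLevel(logging.WARNING)


@pytest.fixture(scope="session")
def table():
    return fx.build_attenuation_table()


@pytest.fixture(scope="session")
def materials():
    return fx.make_default_materials()


@pytest.fixture(scope="session")
def beam_suite(table, materials):
    return fx.make_beam_suite(table, materials)


@pytest.fixture(scope="session")
def default_grid(table, materials, beam_suite):
    """The frozen replica grid run once per session (analytic, <10 s)."""
    from portalcontrast.pipeline import run_experiment_grid

    cfg = fx.default_grid_config()
    points, series = run_experiment_grid(
        cfg, material_registry=materials, table=table, spectra=beam_suite
    )
    return cfg, points, series
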