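import numpy as np
import pytest

from wntquant import concentrations as conc
from wntquant import model as wmodel
from wntquant import pipeline as wpipe
from wntquant import synthetic as synth
from wntquant.volumes import VoxelCalibration


@pytest.fixture(scope="session")
def lee_params() -> wmodel.ReactionParameters:
    return wmodel.load_parameters()


@pytest.fixture(scope="session")
def cell_lines() -> dict:
    return conc.load_cell_lines()


@pytest.fixture(scope="session")
def all_retention_reports(lee_params, cell_lines) -> dict[str, wmodel.RetentionReport]:
    """Two-phase calibration for Xenopus plus the five mammalian lines."""
    reports = {"Xenopus": wmodel.run_calibration(
        wmodel.xenopus_input(lee_params), lee_params)}
    for name in cell_lines:
        inp = wpipe.calibration_input_for_line(name, lee_params, cell_lines)
        reports[name] = wmodel.run_calibration(inp, lee_params)
    return reports


@pytest.fixture
def iso_calibration() -> VoxelCalibration:
    return VoxelCalibration(dx=0.2, dy=0.2, dz=0.2)


@pytest.fixture
def sphere_phantom() -> synth.CellPhantom:
    """A 5-um-radius spherical nucleus/cell phantom centred in its own frame."""
    return synth.CellPhantom(
        center=(8.0, 8.0, 8.0),
        cell_semiaxes=(5.0, 5.0, 5.0),
        nucleus_semiaxes=(3.0, 3.0, 3.0),
        shell_thickness=1.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
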