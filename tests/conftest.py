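import numpy as np
import pandas as pd
import pytest

from mbecflow import pipeline as pl
from mbecflow import simulate as sim
from mbecflow.spectra import default_model


@pytest.fixture(scope="session")
def model():
    return default_model()


def _study(tmp_path_factory, design: str, seed: int):
    study_dir = tmp_path_factory.mktemp(f"study_{design}")
    out_dir = tmp_path_factory.mktemp(f"results_{design}")
    metadata = sim.generate_study(design, study_dir, seed=seed)
    outputs = pl.run_study(study_dir, out_dir, pl.StudyConfig())
    return {"study_dir": study_dir, "out_dir": out_dir,
            "metadata": metadata, **outputs}


@pytest.fixture(scope="session")
def exvivo_study(tmp_path_factory):
    return _study(tmp_path_factory, "exvivo", seed=11)


@pytest.fixture(scope="session")
def moi_study(tmp_path_factory):
    return _study(tmp_path_factory, "moi", seed=13)


@pytest.fixture(scope="session")
def cgd_study(tmp_path_factory):
    return _study(tmp_path_factory, "cgd", seed=5)


@pytest.fixture(scope="session")
def invivo_study(tmp_path_factory):
    return _study(tmp_path_factory, "invivo", seed=7)
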