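import numpy as np
import pytest

import twoflash as tf
from twoflash import synthetic_cohort as sc


@pytest.fixture(scope="session")
def layout103():
    return tf.build_hex_layout("veris103")


@pytest.fixture(scope="session")
def layout7(layout103):
    """Seven-hexagon patch (rings 0-1) for fast signal fixtures."""
    return tf.build_hex_layout(layout103.to_frame().query("ring <= 1"))


@pytest.fixture(scope="session")
def mseq13():
    return tf.generate_msequence(13, n_channels=103)


@pytest.fixture(scope="session")
def schedule13(mseq13):
    return tf.build_frame_schedule(mseq13)


@pytest.fixture(scope="session")
def mseq8():
    return tf.generate_msequence(8, n_channels=7)


@pytest.fixture(scope="session")
def schedule8(mseq8):
    return tf.build_frame_schedule(mseq8)


@pytest.fixture(scope="session")
def hex_masks(layout103):
    return {"central10": tf.central_hexagons(layout103, 1),
            "central15": tf.central_hexagons(layout103, 2)}


@pytest.fixture(scope="session")
def hex_masks7(layout7):
    central = {"central10": tf.central_hexagons(layout7, 1),
               "central15": tf.central_hexagons(layout7, 1)}
    return central


@pytest.fixture(scope="session")
def point_table():
    return tf.g2_point_table()


@pytest.fixture(scope="session")
def sap_masks(point_table):
    return {"central10": tf.select_sap_points(point_table, "central10"),
            "central15": tf.select_sap_points(point_table, "central15")}


@pytest.fixture(scope="session")
def default_design():
    return sc.CohortDesign()


@pytest.fixture(scope="session")
def fast_cohort(default_design, schedule13, layout103):
    """One default 42-eye cohort in feature-level mode, reused read-only."""
    rng = np.random.default_rng(1234)
    return sc.simulate_cohort(default_design, schedule13, layout103,
                              include_trace=False, rng=rng)
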