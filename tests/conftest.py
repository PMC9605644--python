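import numpy as np
import pytest

from gema.control import ControllerState
from gema.gabor import GaborBankConfig, build_bank, matched_grating_response
from gema.metrics import confusion_counts, dice
from gema.preprocess import PreprocessConfig
from gema.segment import GemaParams, segment_gema, segment_gradient
from gema.synthetic import SyntheticConfig, generate_sequence


@pytest.fixture(scope="session")
def bank_and_ref():
    config = GaborBankConfig()
    return build_bank(config), matched_grating_response(config)


@pytest.fixture(scope="session")
def default_growth_sequence():
    """The default 20-frame growth fixture (coverage 0.1 -> 0.9, seed 0)."""
    return generate_sequence(SyntheticConfig())


@pytest.fixture(scope="session")
def small_growth_sequence():
    """A reduced fixture for cheap end-to-end tests."""
    config = SyntheticConfig(
        height=128, width=128, n_frames=6, coverage_start=0.15, coverage_end=0.7,
        cell_radius_range=(10.0, 18.0), faint_margin_px=2.0, edge_softness_px=3.0,
        seed=3,
    )
    return generate_sequence(config)


@pytest.fixture(scope="session")
def default_growth_run(default_growth_sequence, bank_and_ref):
    """Both engines run over the default growth fixture.

    Returns dict with per-frame Dice for each engine, the percent-cells
    trace, scheduled thresholds and the true coverage curve.
    """
    pairs, truth = default_growth_sequence
    bank, ref = bank_and_ref
    pre = PreprocessConfig()
    params = GemaParams()
    state = ControllerState(mode="growth")
    gema_dice, grad_dice, pct, thresholds, cvs = [], [], [], [], []
    for frame, gold in pairs:
        mask, state, row = segment_gema(
            frame, state, pre, bank, params, bank_reference_response=ref
        )
        gema_dice.append(dice(confusion_counts(mask, gold)))
        pct.append(row.percent_cells)
        thresholds.append(row.threshold)
        cvs.append(row.cv)
        grad_dice.append(dice(confusion_counts(segment_gradient(frame, pre), gold)))
    return {
        "truth": truth,
        "gema_dice": gema_dice,
        "grad_dice": grad_dice,
        "percent_cells": pct,
        "thresholds": thresholds,
        "cvs": cvs,
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
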