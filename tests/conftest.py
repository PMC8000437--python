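"""Shared fixtures: one calibrated config and one default cohort per session."""

import logging

import numpy as np
import pandas as pd
import pytest

import macrohier as mh
from macrohier.cohort import COLUMNS

logging.getLogger("macrohier").setLevel(logging.ERROR)


@pytest.fixture(scope="session")
def default_cfg():
    return mh.default_config()


@pytest.fixture(scope="session")
def grid(default_cfg):
    return mh.default_grid(default_cfg)


@pytest.fixture(scope="session")
def cohort912(default_cfg, grid):
    """One default synthetic cohort of n = 912 (seed 17)."""
    import dataclasses
    cfg = dataclasses.replace(default_cfg, seed=17)
    return mh.generate_cohort(cfg, grid=grid)


def make_toy_cohort(n: int, **overrides) -> mh.CohortTable:
    """Minimal valid cohort with constant filler columns.

    ``overrides`` replace individual columns (arrays of length n); birthweight
    and the outcome bands must be overridden together when outcomes matter.
    """
    height = np.full(n, 165.0)
    bmi = np.full(n, 22.0)
    weight = bmi * (height / 100.0) ** 2
    base = {
        "maternal_age_years": np.full(n, 33.0),
        "height_cm": height,
        "prepreg_weight_kg": weight,
        "prepreg_bmi": bmi,
        "gwg_kg": np.full(n, 13.0),
        "parity": np.zeros(n, dtype=int),
        "fetal_sex": np.array(["daughter"] * n, dtype=object),
        "gestational_age_weeks": np.full(n, 39, dtype=int),
        "gdm": np.array(["none"] * n, dtype=object),
        "prior_macrosomia": np.array(["no"] * n, dtype=object),
        "prior_gdm": np.array(["no"] * n, dtype=object),
        "prior_cesarean": np.array(["no"] * n, dtype=object),
        "family_dm_mother": np.array(["none"] * n, dtype=object),
        "family_dm_father": np.array(["none"] * n, dtype=object),
        "smoking": np.array(["never"] * n, dtype=object),
        "education": np.array(["ge12"] * n, dtype=object),
        "financial_status": np.array(["higher"] * n, dtype=object),
        "residence": np.array(["village"] * n, dtype=object),
        "marital_status": np.array(["married"] * n, dtype=object),
        "folic_acid": np.array(["yes"] * n, dtype=object),
        "multivitamin": np.array(["yes"] * n, dtype=object),
        "interpregnancy_interval": np.array(["primigravida"] * n, dtype=object),
        "birthweight_g": np.full(n, 3400.0),
        "macrosomia": np.zeros(n, dtype=int),
        "weight_band": np.array(["2500_4000"] * n, dtype=object),
        "lga_band": np.array(["10_90"] * n, dtype=object),
    }
    base.update(overrides)
    table = mh.CohortTable(pd.DataFrame({c: base[c] for c in COLUMNS}))
    table.validate()
    return table
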