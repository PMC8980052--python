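import numpy as np
import pandas as pd
import pytest

from tbimine import synthetic_data as sd


def _visit(pid, pair, role, date, codes, **kw):
    row = {
        "patient_id": pid,
        "pair_id": pair,
        "role": role,
        "sex": kw.get("sex", "M"),
        "age_band": kw.get("age_band", "35-49"),
        "rural": kw.get("rural", 0),
        "income_q": kw.get("income_q", 3),
        "visit_date": pd.Timestamp(date),
        "setting": "ED",
        "codes": codes,
    }
    return row


@pytest.fixture
def tiny_visits():
    """Two matched pairs with hand-placed dates and codes."""
    rows = [
        # case A: non-TBI visit, then first TBI visit (index), then another TBI
        _visit("A", "M0", "case", "2010-01-10", "I10"),
        _visit("A", "M0", "case", "2010-06-15", "S060;W19"),
        _visit("A", "M0", "case", "2010-08-01", "S060"),
        # reference B: three visits, midpoint = second
        _visit("B", "M0", "reference", "2009-01-01", "E11"),
        _visit("B", "M0", "reference", "2010-06-01", "I10;I10"),
        _visit("B", "M0", "reference", "2011-01-01", "K70"),
        # case C: TBI at first visit
        _visit("C", "M1", "case", "2012-03-01", "S061;V43;W22"),
        _visit("C", "M1", "case", "2012-03-10", "J15"),
        # reference D: four visits, midpoint = earlier middle (second)
        _visit("D", "M1", "reference", "2011-01-01", "A00"),
        _visit("D", "M1", "reference", "2011-06-01", "B01"),
        _visit("D", "M1", "reference", "2012-01-01", "C02"),
        _visit("D", "M1", "reference", "2012-06-01", "D03"),
    ]
    return pd.DataFrame(rows)


@pytest.fixture
def null_config():
    """Global-null simulation: no planted factors, equal prevalences."""
    return sd.SimulationConfig(
        n_pairs=300,
        code_universe=sd.default_code_universe(50),
        background_code_prevalence=0.02,
        seed=11,
    )


def make_planted_config(n_pairs=2000, seed=0, rho_links=()):
    """Three disjoint event factors + one pre-injury factor, optional links."""
    universe = sd.default_code_universe(60)
    planted = [
        sd.PlantedFactor("PREA", "pre_injury", tuple(universe[0:3]), 0.12, 2.0, 0.8),
        sd.PlantedFactor("EVA", "event", tuple(universe[10:13]), 0.10, 3.0, 0.8),
        sd.PlantedFactor("EVB", "event", tuple(universe[20:23]), 0.10, 2.5, 0.8),
        sd.PlantedFactor("EVC", "event", tuple(universe[30:33]), 0.10, 3.0, 0.8),
    ]
    cfg = sd.SimulationConfig(
        n_pairs=n_pairs,
        code_universe=universe,
        planted_factors=planted,
        background_code_prevalence=0.01,
        seed=seed,
    )
    for pre, tgt, rho in rho_links:
        cfg = sd.plant_transition(cfg, pre, tgt, rho)
    return cfg


@pytest.fixture
def planted_config():
    return make_planted_config(n_pairs=1000, seed=5)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
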