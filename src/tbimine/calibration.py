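"""Empirical FDR calibration of the screening stage on null cohorts.

Generates matched cohorts with no planted structure (every diagnosis code
equally prevalent in cases and references), runs the full visit-table ->
phase -> binary-matrix -> matched McNemar -> BY path, and records the
false-discovery proportion per replicate.  Because the whole code family
is null, every discovery is false, so the FDP is 1 whenever anything is
discovered and 0 otherwise; the mean over replicates estimates the
realised FDR of the screening stage.

The screened family is restricted to the simulated code universe: the
index-event and external-cause codes that define the cases are structural
(present in every case by construction) and carry no null hypothesis.
"""

from __future__ import annotations

import numpy as np

from . import cohort, screening, synthetic_data

__all__ = ["null_false_discovery_proportions"]


def null_false_discovery_proportions(
    n_replicates: int = 200,
    n_pairs: int = 2000,
    n_codes: int = 200,
    alpha: float = 0.05,
    seed: int = 0,
    require_or_gt_1: bool = False,
) -> np.ndarray:
    """FDP per replicate of the screening stage under the global null."""
    universe = synthetic_data.default_code_universe(n_codes)
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31)
    fdps = np.empty(n_replicates)
    for i, s in enumerate(seeds):
        cfg = synthetic_data.SimulationConfig(
            n_pairs=n_pairs, code_universe=universe, seed=int(s)
        )
        visits, _ = synthetic_data.generate_cohort(cfg)
        idx = cohort.assign_index_dates(visits)
        phased = cohort.assign_phases(visits, idx)
        mat = cohort.build_code_matrix(phased, "event_window", sorted(idx["patient_id"]))
        mat = mat[[c for c in mat.columns if c in universe]]
        cases = idx[idx["role"] == "case"]
        refs = idx[idx["role"] == "reference"]
        mc = mat.loc[cases["patient_id"]].set_axis(cases["pair_id"].to_numpy(), axis=0)
        mr = mat.loc[refs["patient_id"]].set_axis(refs["pair_id"].to_numpy(), axis=0)
        rec = screening.screen_codes(
            mc, mr, alpha=alpha, require_or_gt_1=require_or_gt_1
        )
        discoveries = int(rec["significant"].sum())
        fdps[i] = 1.0 if discoveries > 0 else 0.0  # all codes are null
    return fdps
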