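"""End-to-end runner: simulate/load -> cohort -> screen -> factors -> maps.

Reproduces the six-stage analysis on one visit table: phase assignment and
50/25/25 pair-level splitting, matched McNemar + BY screening on the
training split with validation-split replication, principal-components
factor analysis of the retained codes (factor count chosen by the AUC
loop), conditional logistic ORs on the test split, and FDR-masked,
Ward-clustered transition heatmaps per split with a cross-split
concordance report.

All randomness flows from one root seed through named substreams
(simulation, splitting), so a fixed seed reproduces every numeric output
bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import association, cohort, factors, screening, synthetic_data, transitions

__all__ = ["PipelineConfig", "run_pipeline", "default_mapping_path"]

_AGE_ORD = {b: i for i, b in enumerate(("0-17", "18-34", "35-49", "50-64", "65-79", "80+"))}


def default_mapping_path(name: str) -> Path:
    """Path to a packaged mapping/fixture file (editable stubs)."""
    return Path(str(resources.files("tbimine").joinpath("data", name)))


@dataclass
class PipelineConfig:
    """All pipeline constants in one place.

    The numeric defaults are the analysis constants: a 61-day event window
    (+/-30 days), a 5-year pre-injury phase, FDR alpha 0.05 with BY
    adjustment, loading cutoff 0.2, minimum reference carrier count 6 and
    a 50/25/25 pair-level split.
    """

    output_dir: str = "runs/latest"
    visits_path: str | None = None  # CSV/Parquet; None => simulate
    simulation: synthetic_data.SimulationConfig | None = None
    severity_map_path: str | None = None  # None => packaged stub
    cause_map_path: str | None = None
    preinjury_factors_path: str | None = None  # None => planted truth (simulated)
    event_halfwidth_days: int = 30
    preinjury_years: int = 5
    fdr_alpha: float = 0.05
    fdr_method: str = "by"
    or_method: str = "conditional"
    loading_cutoff: float = 0.2
    min_ref_count: int = 6
    n_factors: int | str = "auto"
    # the index-event code family is tautologically present in every case;
    # keeping it would create constant factor scores in the case cohort
    exclude_index_codes_from_factors: bool = True
    k_candidates: tuple[int, ...] = (1, 2, 3, 4, 5, 6, 7, 8)
    split_fractions: tuple[float, float, float] = (0.5, 0.25, 0.25)
    rotation: str = "varimax"
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 < self.fdr_alpha <= 1.0:
            raise ValueError("fdr_alpha outside (0, 1]")
        if not 0.0 < self.loading_cutoff < 1.0:
            raise ValueError("loading_cutoff outside (0, 1)")
        if abs(sum(self.split_fractions) - 1.0) > 1e-9:
            raise ValueError("split fractions must sum to 1")
        if self.min_ref_count < 0:
            raise ValueError("min_ref_count must be nonnegative")
        if self.visits_path is None and self.simulation is None:
            # default desk-scale simulation with a small planted structure
            self.simulation = _default_simulation(self.seed)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            factors_ = [
                synthetic_data.PlantedFactor(
                    member_codes=tuple(f.pop("member_codes")), **f
                )
                for f in sim.pop("planted_factors", [])
            ]
            links = [
                synthetic_data.TransitionLink(**l)
                for l in sim.pop("transition_links", [])
            ]
            cfg.simulation = synthetic_data.SimulationConfig(
                planted_factors=factors_, transition_links=links, **sim
            )
        return cfg


def _default_simulation(seed: int) -> synthetic_data.SimulationConfig:
    """Desk-scale demo cohort: 2,000 pairs, 200 codes, 3+3 planted factors."""
    universe = synthetic_data.default_code_universe(200)
    # disjoint member-code blocks spread across the universe
    blocks = [tuple(universe[i * 30 : i * 30 + 3]) for i in range(6)]
    planted = [
        synthetic_data.PlantedFactor("PRE1", "pre_injury", blocks[0], 0.10, 2.0, 0.7),
        synthetic_data.PlantedFactor("PRE2", "pre_injury", blocks[1], 0.08, 2.5, 0.7),
        synthetic_data.PlantedFactor("PRE3", "pre_injury", blocks[2], 0.08, 2.0, 0.7),
        synthetic_data.PlantedFactor("EV1", "event", blocks[3], 0.10, 3.0, 0.7),
        synthetic_data.PlantedFactor("EV2", "event", blocks[4], 0.08, 2.5, 0.7),
        synthetic_data.PlantedFactor("EV3", "event", blocks[5], 0.08, 3.0, 0.7),
    ]
    cfg = synthetic_data.SimulationConfig(
        n_pairs=2000, code_universe=universe, planted_factors=planted,
        background_code_prevalence=0.01, seed=seed,
    )
    cfg = synthetic_data.plant_transition(cfg, "PRE1", "EV1", 0.4)
    cfg = synthetic_data.plant_transition(cfg, "PRE2", "cause:falls", 0.35)
    cfg = synthetic_data.plant_transition(cfg, "PRE2", "severity:severe", 0.3)
    cfg = synthetic_data.plant_transition(cfg, "PRE3", "EV2", 0.3)
    return cfg


def _covariate_frame(index_dates: pd.DataFrame, role: str) -> pd.DataFrame:
    sub = index_dates[index_dates["role"] == role].set_index("pair_id")
    return pd.DataFrame(
        {
            "sex_male": (sub["sex"] == "M").astype(int),
            "age_ord": sub["age_band"].map(_AGE_ORD).astype(float),
            "rural": sub["rural"].astype(int),
            "income_q": sub["income_q"].astype(float),
        },
        index=sub.index,
    )


def _pair_matrix(matrix: pd.DataFrame, index_dates: pd.DataFrame, role: str,
                 pairs) -> pd.DataFrame:
    """Subset a patient-indexed matrix to one role, reindexed by pair id."""
    sub = index_dates[(index_dates["role"] == role) & index_dates["pair_id"].isin(pairs)]
    out = matrix.loc[sub["patient_id"]]
    out.index = pd.Index(sub["pair_id"].to_numpy(), name="pair_id")
    return out.sort_index()


def _hash_file(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _load_preinjury_definitions(path) -> list[factors.FactorDefinition]:
    with open(path) as fh:
        raw = json.load(fh)
    return [
        factors.FactorDefinition(
            factor_id=f["factor_id"], member_codes=tuple(f["codes"]),
            cutoff=0.0, label=f.get("label", ""),
        )
        for f in raw["factors"]
    ]


def run_pipeline(config: PipelineConfig) -> dict:
    """Run all stages; write stage outputs and a manifest to the run directory.

    Returns the manifest dictionary (stage counts, chosen parameters, file
    hashes).  Any stage failure raises with the stage name in the message.
    """
    config.validate()
    out_dir = Path(config.output_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "files": {}}

    def _stage(name):
        class _Ctx:
            def __enter__(self):
                return None

            def __exit__(self, exc_type, exc, tb):
                if exc is not None:
                    raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
                return False

        return _Ctx()

    # ------------------------------------------------------------------ input
    truth = None
    with _stage("input"):
        if config.visits_path is not None:
            p = Path(config.visits_path)
            visits = (
                pd.read_parquet(p) if p.suffix == ".parquet" else pd.read_csv(p)
            )
            visits["visit_date"] = pd.to_datetime(visits["visit_date"])
        else:
            visits, truth = synthetic_data.generate_cohort(config.simulation)
            visits.to_csv(out_dir / "visits.csv", index=False)
            truth.to_json(out_dir / "ground_truth.json")

    # ----------------------------------------------------------------- cohort
    with _stage("cohort"):
        index_dates = cohort.assign_index_dates(visits)
        phased = cohort.assign_phases(
            visits, index_dates,
            event_halfwidth_days=config.event_halfwidth_days,
            preinjury_years=config.preinjury_years,
        )
        patients = sorted(index_dates["patient_id"])
        event_matrix = cohort.build_code_matrix(phased, "event_window", patients)
        pre_matrix = cohort.build_code_matrix(phased, "pre_injury", patients)
        split = cohort.split_cohort(
            index_dates["pair_id"], config.split_fractions, seed=config.seed + 1
        )
        split.rename_axis("pair_id").to_frame().to_csv(out_dir / "splits.csv")
        sev_path = config.severity_map_path or default_mapping_path("severity_map.csv")
        cause_path = config.cause_map_path or default_mapping_path("cause_map.csv")
        labels = cohort.label_severity_and_cause(
            phased, cohort.load_mapping(sev_path), cohort.load_mapping(cause_path)
        )
        manifest["stages"]["cohort"] = {
            "n_patients": len(patients),
            "n_pairs": int(index_dates["pair_id"].nunique()),
            "codes_event": int(event_matrix.shape[1]),
            "codes_pre": int(pre_matrix.shape[1]),
        }

    pairs_of = {s: split.index[split == s] for s in ("train", "validation", "test")}

    # -------------------------------------------------------------- screening
    with _stage("screening"):
        screens = {}
        for s in ("train", "validation"):
            mc = _pair_matrix(event_matrix, index_dates, "case", pairs_of[s])
            mr = _pair_matrix(event_matrix, index_dates, "reference", pairs_of[s])
            screens[s] = screening.screen_codes(
                mc, mr, alpha=config.fdr_alpha,
                fdr_method=config.fdr_method, or_method=config.or_method,
            )
            screens[s].to_csv(out_dir / f"screening_{s}.tsv", sep="\t")
        retained_codes = screening.replicate_filter(screens["train"], screens["validation"])
        if not retained_codes:
            raise RuntimeError("no code survived train+validation replication")
        manifest["stages"]["screening"] = {
            "codes_tested": int(len(screens["train"])),
            "codes_significant_train": int(screens["train"]["significant"].sum()),
            "codes_significant_validation": int(screens["validation"]["significant"].sum()),
            "codes_validated": len(retained_codes),
        }

    # ---------------------------------------------------------------- factors
    with _stage("factors"):
        if config.exclude_index_codes_from_factors:
            index_trunc = tuple({c[:3] for c in synthetic_data.TBI_CODES})
            retained_codes = [c for c in retained_codes if not c.startswith(index_trunc)]
            if not retained_codes:
                raise RuntimeError("only index-event codes survived replication")
        train_case = _pair_matrix(event_matrix, index_dates, "case", pairs_of["train"])
        train_ref = _pair_matrix(event_matrix, index_dates, "reference", pairs_of["train"])
        tc, tr = train_case[retained_codes], train_ref[retained_codes]
        if config.n_factors == "auto":
            diag = factors.select_k(
                tc, tr,
                [k for k in config.k_candidates if k <= len(retained_codes)],
                cutoff=config.loading_cutoff, rotation=config.rotation,
            )
            k = diag["chosen_k"]
            pd.DataFrame(
                {
                    "k": list(diag["auc_by_k"]),
                    "auc": list(diag["auc_by_k"].values()),
                }
            ).to_csv(out_dir / "k_selection.tsv", sep="\t", index=False)
        else:
            diag = None
            k = int(config.n_factors)
        model = factors.fit_factor_model(
            pd.concat([tc, tr]), k, rotation=config.rotation
        )
        model.loadings.to_csv(out_dir / "loadings.tsv", sep="\t")
        pd.DataFrame(
            {"eigenvalue": model.eigenvalues, "cumulative_variance": model.cumulative_variance}
        ).to_csv(out_dir / "scree.tsv", sep="\t", index_label="component")
        defs, unassigned = factors.define_factors(model, cutoff=config.loading_cutoff)
        event_scores = factors.score_factors(event_matrix[retained_codes], defs)
        roles = index_dates.set_index("patient_id")["role"]
        retained_f, excluded_f = factors.exclude_rare_factors(
            event_scores, roles, min_ref_count=config.min_ref_count
        )
        event_scores = event_scores[retained_f]
        defs = [d for d in defs if d.factor_id in retained_f]
        with open(out_dir / "factors.json", "w") as fh:
            json.dump(
                {
                    "k": k,
                    "retained": retained_f,
                    "excluded_rare": excluded_f,
                    "unassigned_codes": unassigned,
                    "definitions": [dataclasses.asdict(d) for d in defs],
                },
                fh, indent=1,
            )
        manifest["stages"]["factors"] = {
            "k": int(k),
            "codes_meeting_cutoff": int(len(retained_codes) - len(unassigned)),
            "factors_retained": len(retained_f),
            "factors_excluded_rare": len(excluded_f),
        }

    # ------------------------------------------------------------ association
    with _stage("association"):
        sc = _pair_matrix(event_scores, index_dates, "case", pairs_of["test"])
        sr = _pair_matrix(event_scores, index_dates, "reference", pairs_of["test"])
        cov_c = _covariate_frame(index_dates, "case").reindex(sc.index)
        cov_r = _covariate_frame(index_dates, "reference").reindex(sr.index)
        assoc = association.per_exposure_associations(sc, sr, cov_c, cov_r)
        assoc.to_csv(out_dir / "association_test.tsv", sep="\t")
        manifest["stages"]["association"] = {"factors_fitted": int(len(assoc))}

    # ------------------------------------------------------------ transitions
    with _stage("transitions"):
        if config.preinjury_factors_path is not None:
            pre_defs = _load_preinjury_definitions(config.preinjury_factors_path)
        elif truth is not None and config.simulation.planted_factors:
            pre_defs = [
                factors.FactorDefinition(f.factor_id, f.member_codes, 0.0)
                for f in config.simulation.planted_factors
                if f.phase == "pre_injury"
            ]
        else:
            raise RuntimeError("no pre-injury factor definitions available")
        pre_defs = [
            d for d in pre_defs
            if any(c in pre_matrix.columns for c in d.member_codes)
        ]
        if not pre_defs:
            raise RuntimeError("no pre-injury factor has codes in the data")
        pre_scores = factors.score_factors(pre_matrix, pre_defs)
        case_ids = index_dates.loc[index_dates["role"] == "case"].set_index("pair_id")
        maps = {}
        for s in ("train", "validation", "test"):
            ids = case_ids.loc[case_ids.index.isin(pairs_of[s]), "patient_id"]
            tm = transitions.transition_map(
                pre_scores.loc[ids], event_scores.loc[ids],
                alpha=config.fdr_alpha, method=config.fdr_method,
            )
            maps[s] = tm
            transitions.render_heatmap(
                tm, out_dir / f"heatmap_{s}.png", out_dir / f"heatmap_{s}.tsv",
                title=f"pre-injury x event factors ({s})",
            )
            gm = transitions.grouped_transition_map(
                pre_scores.loc[ids], labels.loc[ids],
                alpha=config.fdr_alpha, method=config.fdr_method,
            )
            transitions.render_heatmap(
                gm, out_dir / f"heatmap_grouped_{s}.png",
                out_dir / f"heatmap_grouped_{s}.tsv",
                title=f"pre-injury factors x severity/cause ({s})",
            )
        concordance = transitions.compare_splits(maps)
        concordance.to_csv(out_dir / "concordance.tsv", sep="\t", index=False)
        manifest["stages"]["transitions"] = {
            "significant_cells": {
                s: int((maps[s].masked.to_numpy() != 0).sum()) for s in maps
            },
        }

    for f in sorted(out_dir.glob("*.tsv")) + sorted(out_dir.glob("*.json")):
        if f.name != "manifest.json":
            manifest["files"][f.name] = _hash_file(f)
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, default=str)
    return manifest
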