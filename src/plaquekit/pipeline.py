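"""End-to-end analysis pipeline and run configuration.

Executes metrics -> lesions -> agreement -> interaction models for the
requested analysis levels and writes a reproducible report bundle: tidy
CSV tables (the machine-readable analogues of the multi-level comparison
tables), ICC figure data, model JSON reports, spread-out plot exports and
a run manifest with the seed, configuration hash and library versions.
Identical configuration + seed reproduces every output byte-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .agreement import (
    AgreementResult,
    IccModelSpec,
    bland_altman,
    compare_adjusted_icc,
    icc_band,
    icc_heterogeneity,
    icc_mixed,
    stratify,
    wilcoxon_paired,
    DegenerateDataError,
)
from .data_model import (
    MatchedDataset,
    Tissue,
    build_matched_dataset,
    read_frame_table,
    validate_dataset,
    write_frame_table,
)
from .interaction import difference_curves, fit_ols_interaction, fit_prop_odds
from .lesion_analysis import LesionPolicy, analyze_lesions
from .plaque_metrics import (
    build_spreadout,
    render_spreadout,
    segment_metrics,
    spreadout_to_csv,
)
from .synthetic import generate_cohort, get_preset

logger = logging.getLogger("plaquekit")

__all__ = ["RunConfig", "run_pipeline"]

_LEVEL_KNOTS = {"segment": 3, "lesion": 3, "frame": 5}

SEGMENT_VARS = ["lumen_volume", "vessel_volume", "tav", "pav",
                "lcbi", "cabi", "max_lcbi_4mm"]
LESION_VARS = ["mla", "max_pb", "ref_lumen_area", "ref_vessel_area",
               "remodelling_index", "lcbi", "cabi", "max_lcbi_4mm"]
FRAME_VARS = ["lumen_area", "vessel_area", "plaque_area", "pb",
              "lipid_arc_frac", "ca_arc_frac"]


@dataclass
class RunConfig:
    """Declarative analysis configuration (audit-able as a YAML file)."""

    input_csv: str | None = None  # frame-table CSV; None -> simulate
    preset: str = "paper-like"  # synthetic preset when input_csv is None
    levels: list[str] = field(default_factory=lambda: ["segment", "lesion", "frame"])
    stratification: str = "terciles"
    knots: dict[str, int] = field(default_factory=lambda: dict(_LEVEL_KNOTS))
    n_boot: int = 2000
    seed: int = 0
    output_dir: str = "plaquekit_report"
    pb_threshold: float = 40.0
    min_lesion_frames: int = 3
    merge_gap_mm: float = 5.0
    reference_flank_mm: float = 5.0
    reference_anchor: str = "min_pb"
    make_plots: bool = True
    decile_sensitivity: bool = True

    def __post_init__(self) -> None:
        for level, k in self.knots.items():
            if k not in (3, 5):
                raise ValueError(f"knots for {level} must be 3 or 5, got {k}")
        if self.seed is None:
            raise ValueError("seed is mandatory")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        doc = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        return cls(**doc)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def lesion_policy(self) -> LesionPolicy:
        return LesionPolicy(
            pb_threshold=self.pb_threshold,
            min_frames=self.min_lesion_frames,
            merge_gap_mm=self.merge_gap_mm,
            reference_flank_mm=self.reference_flank_mm,
            reference_anchor=self.reference_anchor,
        )


# ---------------------------------------------------------------------------
# Level tables
# ---------------------------------------------------------------------------

def _arc_frac(frame, flag: Tissue) -> float:
    return float(((frame.tissue_bins & int(flag)) > 0).mean())


def segment_table(dataset: MatchedDataset) -> pd.DataFrame:
    rows = []
    for (subject, vessel), nirs_seg, cta_seg in dataset.segments():
        for seg in (nirs_seg, cta_seg):
            m = segment_metrics(seg)
            rows.append(
                {
                    "subject_id": subject,
                    "vessel_id": vessel,
                    "modality": seg.modality.value,
                    **asdict(m),
                }
            )
    return pd.DataFrame(rows)


def lesion_table(dataset: MatchedDataset, policy: LesionPolicy) -> pd.DataFrame:
    rows = []
    for li, (nirs_l, cta_l) in enumerate(analyze_lesions(dataset, policy)):
        for les in (nirs_l, cta_l):
            rows.append(
                {
                    "lesion_id": f"{les.subject_id}:{les.vessel_id}:L{li}",
                    "subject_id": les.subject_id,
                    "vessel_id": les.vessel_id,
                    "modality": les.modality,
                    "start": les.span.start,
                    "end": les.span.end,
                    "length_mm": les.length,
                    "mla": les.geometry.mla,
                    "max_pb": les.geometry.max_pb,
                    "ref_lumen_area": les.geometry.ref_lumen_area,
                    "ref_vessel_area": les.geometry.ref_vessel_area,
                    "remodelling_index": les.geometry.remodelling_index,
                    "one_sided_reference": les.geometry.one_sided_reference,
                    "reference_missing": les.geometry.reference_missing,
                    "lcbi": les.lcbi,
                    "cabi": les.cabi,
                    "max_lcbi_4mm": les.max_lcbi_4mm,
                    "mean_ca_area": les.mean_ca_area,
                }
            )
    return pd.DataFrame(rows)


def frame_table(dataset: MatchedDataset) -> pd.DataFrame:
    rows = []
    for fi, (nirs, cta) in enumerate(dataset.pairs):
        ca_area_cta = (cta.tissue_areas or {}).get("CA", np.nan)
        for f in (nirs, cta):
            rows.append(
                {
                    "frame_id": f"F{fi:06d}",
                    "subject_id": f.subject_id,
                    "vessel_id": f.vessel_id,
                    "modality": f.modality.value,
                    "position_mm": f.position,
                    "lumen_area": f.lumen_area,
                    "vessel_area": f.vessel_area,
                    "plaque_area": f.plaque_area,
                    "pb": f.plaque_burden,
                    "lipid_arc_frac": _arc_frac(f, Tissue.LIPID),
                    "ca_arc_frac": _arc_frac(f, Tissue.CA),
                    "ca_area_cta": ca_area_cta,
                }
            )
    return pd.DataFrame(rows)


def _wide(level_df: pd.DataFrame, id_col: str, variables: list[str],
          ca_col: str) -> pd.DataFrame:
    """Pivot a per-modality level table to one row per target with
    ``<var>_nirs`` / ``<var>_cta`` columns plus the CTA calcium
    stratifier."""
    nirs = level_df[level_df["modality"] == "NIRS_IVUS"].set_index(id_col)
    cta = level_df[level_df["modality"] == "CTA"].set_index(id_col)
    out = pd.DataFrame(index=nirs.index)
    out["subject_id"] = nirs["subject_id"]
    for v in variables:
        out[f"{v}_nirs"] = nirs[v]
        out[f"{v}_cta"] = cta[v]
    out["ca_strat"] = cta[ca_col]
    return out.reset_index(names="target_id")


# ---------------------------------------------------------------------------
# Agreement stage
# ---------------------------------------------------------------------------

def _agree_one(x: np.ndarray, y: np.ndarray, variable: str, level: str,
               stratum: str, ba_mode: str) -> dict:
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    row = {"variable": variable, "level": level, "stratum": stratum,
           "n": int(x.size)}
    try:
        row["p_value"] = wilcoxon_paired(x, y)
    except (DegenerateDataError, ValueError):
        row["p_value"] = np.nan
    try:
        bias, lo, hi = bland_altman(x - y, mode=ba_mode)
    except ValueError:
        bias = lo = hi = np.nan
    row.update({"bias": bias, "loa_low": lo, "loa_high": hi, "ba_mode": ba_mode})
    return row


def _icc_long(wide: pd.DataFrame, variable: str) -> pd.DataFrame:
    ok = np.isfinite(wide[f"{variable}_nirs"]) & np.isfinite(wide[f"{variable}_cta"])
    sub = wide[ok]
    long = pd.DataFrame(
        {
            "subject": np.repeat(sub["target_id"].to_numpy(), 2),
            "patient": np.repeat(sub["subject_id"].to_numpy(), 2),
            "modality": np.tile(["NIRS_IVUS", "CTA"], len(sub)),
            "value": np.column_stack(
                [sub[f"{variable}_nirs"], sub[f"{variable}_cta"]]
            ).ravel(),
            "ca": np.repeat(sub["ca_strat"].to_numpy(), 2),
        }
    )
    return long


def agreement_stage(wide: pd.DataFrame, variables: list[str], level: str,
                    config: RunConfig) -> dict[str, pd.DataFrame]:
    ba_mode = "parametric" if level == "frame" else "nonparametric"
    n_knots = config.knots[level]
    rows, icc_rows, het_rows, dec_rows = [], [], [], []
    strata = stratify(wide["ca_strat"].to_numpy(), config.stratification)
    n_strata = int(strata.max()) + 1
    stratum_names = {3: ["low", "intermediate", "high"]}.get(
        n_strata, [f"g{i}" for i in range(n_strata)]
    )
    for v in variables:
        x = wide[f"{v}_nirs"].to_numpy(dtype=float)
        y = wide[f"{v}_cta"].to_numpy(dtype=float)
        rows.append(_agree_one(x, y, v, level, "all", ba_mode))
        for g in range(n_strata):
            m = strata == g
            rows.append(_agree_one(x[m], y[m], v, level, stratum_names[g], ba_mode))

        long = _icc_long(wide, v)
        unadj = icc_mixed(long, IccModelSpec(cluster="patient"),
                          n_boot=config.n_boot, seed=config.seed)
        try:
            adj = icc_mixed(
                long,
                IccModelSpec(covariate="ca", n_knots=n_knots, cluster="patient"),
                n_boot=config.n_boot, seed=config.seed,
            )
            adj_tuple = (adj.icc, adj.ci, compare_adjusted_icc(unadj, adj))
        except (ValueError, np.linalg.LinAlgError):
            adj_tuple = (np.nan, (np.nan, np.nan), False)
        icc_rows.append(
            {
                "variable": v, "level": level,
                "icc_unadjusted": unadj.icc,
                "icc_unadj_lo": unadj.ci[0], "icc_unadj_hi": unadj.ci[1],
                "band": icc_band(unadj.icc),
                "icc_adjusted": adj_tuple[0],
                "icc_adj_lo": adj_tuple[1][0], "icc_adj_hi": adj_tuple[1][1],
                "adjustment_significant": adj_tuple[2],
                "method": unadj.method, "n": unadj.n_subjects,
            }
        )

        stratum_iccs = []
        for g in range(n_strata):
            ids = set(wide["target_id"][strata == g])
            sub = long[long["subject"].isin(ids)]
            try:
                r = icc_mixed(sub, IccModelSpec(cluster="patient"),
                              n_boot=config.n_boot, seed=config.seed)
                stratum_iccs.append((stratum_names[g], r))
            except ValueError:
                continue
        for name, r in stratum_iccs:
            icc_rows.append(
                {
                    "variable": v, "level": level,
                    "icc_unadjusted": r.icc,
                    "icc_unadj_lo": r.ci[0], "icc_unadj_hi": r.ci[1],
                    "band": icc_band(r.icc),
                    "icc_adjusted": np.nan, "icc_adj_lo": np.nan,
                    "icc_adj_hi": np.nan, "adjustment_significant": False,
                    "method": r.method + f"/{name}", "n": r.n_subjects,
                }
            )
        if len(stratum_iccs) >= 2:
            try:
                het = icc_heterogeneity([(r.icc, r.ci) for _, r in stratum_iccs])
                het_rows.append(
                    {"variable": v, "level": level, "q": het.q, "df": het.df,
                     "p_heterogeneity": het.p_value, "tau2": het.tau2}
                )
            except ValueError:
                pass

        if config.decile_sensitivity:
            try:
                dec = stratify(wide["ca_strat"].to_numpy(), "deciles")
            except ValueError:
                dec = None
            if dec is not None:
                for g in range(int(dec.max()) + 1):
                    ids = set(wide["target_id"][dec == g])
                    sub = long[long["subject"].isin(ids)]
                    try:
                        r = icc_mixed(sub, IccModelSpec(cluster="patient"),
                                      n_boot=0, seed=config.seed)
                    except ValueError:
                        continue
                    dec_rows.append(
                        {"variable": v, "level": level, "decile": g,
                         "icc": r.icc, "band": icc_band(r.icc),
                         "n": r.n_subjects}
                    )
    return {
        "agreement": pd.DataFrame(rows),
        "icc": pd.DataFrame(icc_rows),
        "heterogeneity": pd.DataFrame(het_rows),
        "icc_deciles": pd.DataFrame(dec_rows),
    }


# ---------------------------------------------------------------------------
# Model stage
# ---------------------------------------------------------------------------

def _fit_to_report(fit) -> dict:
    return {
        "level": fit.level,
        "outcome": fit.outcome,
        "model": fit.model,
        "adjusted": fit.adjusted,
        "interaction": fit.interaction,
        "n": fit.n,
        "loglik": fit.loglik,
        "interaction_p": fit.interaction_p,
        "converged": fit.converged,
        "coefficients": {
            k: {"estimate": est, "se": se} for k, (est, se) in fit.coefficients.items()
        },
    }


def model_stage(wide: pd.DataFrame, variables: list[str], level: str,
                config: RunConfig) -> tuple[dict, pd.DataFrame]:
    n_knots = config.knots[level]
    reports = {}
    curves = []
    for v in variables:
        sub = wide[
            np.isfinite(wide[f"{v}_nirs"])
            & np.isfinite(wide[f"{v}_cta"])
            & np.isfinite(wide["ca_strat"])
        ]
        y = sub[f"{v}_nirs"].to_numpy(dtype=float)
        x = sub[f"{v}_cta"].to_numpy(dtype=float)
        ca = sub["ca_strat"].to_numpy(dtype=float)
        try:
            if level == "frame":
                cl = sub["subject_id"].to_numpy()
                unadj = fit_ols_interaction(y, x, cluster=cl, n_knots=n_knots,
                                            level=level, outcome_name=v)
                adj = fit_ols_interaction(y, x, ca, interaction=True, cluster=cl,
                                          n_knots=n_knots, level=level,
                                          outcome_name=v)
            else:
                unadj = fit_prop_odds(y, x, n_knots=n_knots, level=level,
                                      outcome_name=v, compute_se=False)
                adj = fit_prop_odds(y, x, ca, interaction=True, n_knots=n_knots,
                                    level=level, outcome_name=v, compute_se=False)
        except (ValueError, RuntimeError) as exc:
            reports[v] = {"error": str(exc)}
            continue
        reports[v] = {"unadjusted": _fit_to_report(unadj),
                      "adjusted": _fit_to_report(adj)}
        try:
            dc = difference_curves(adj)
            dc.insert(0, "variable", v)
            dc.insert(0, "level", level)
            curves.append(dc)
        except (ValueError, RuntimeError):
            pass
    curve_df = pd.concat(curves, ignore_index=True) if curves else pd.DataFrame()
    return reports, curve_df


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(type(o))


def _write_json(obj, path: Path) -> None:
    path.write_text(
        json.dumps(obj, indent=1, sort_keys=True, default=_json_default),
        encoding="utf-8",
    )


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Execute the full multi-level comparison; returns output paths."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    if config.input_csv is not None:
        frames = read_frame_table(config.input_csv)
        dataset = build_matched_dataset(frames)
        logger.info("loaded %d matched pairs from %s", len(dataset), config.input_csv)
    else:
        spec = get_preset(config.preset)
        spec = type(spec)(**{**asdict(spec), "seed": config.seed})
        dataset, truth = generate_cohort(spec)
        logger.info("simulated %d matched pairs (preset %s)", len(dataset), config.preset)
        p = out / "frame_table.csv"
        write_frame_table([f for pair in dataset.pairs for f in pair], p)
        written["frame_table"] = p
        p = out / "ground_truth.csv"
        truth["frames"].to_csv(p, index=False)
        written["ground_truth"] = p

    violations = validate_dataset(dataset)
    if violations:
        first = violations[0]
        raise ValueError(
            f"validation failed ({len(violations)} violations); first: "
            f"frame {first.frame_key} field {first.field} rule {first.rule}"
        )

    seg_df = segment_table(dataset)
    written["segment_metrics"] = out / "segment_metrics.csv"
    seg_df.to_csv(written["segment_metrics"], index=False)
    logger.info("segment metrics: %d rows", len(seg_df))

    les_df = lesion_table(dataset, config.lesion_policy())
    written["lesion_table"] = out / "lesion_table.csv"
    les_df.to_csv(written["lesion_table"], index=False)
    logger.info("lesions detected: %d", len(les_df) // 2)

    frm_df = frame_table(dataset)
    written["frame_metrics"] = out / "frame_metrics.csv"
    frm_df.to_csv(written["frame_metrics"], index=False)

    level_wide = {}
    if "segment" in config.levels:
        seg_ids = seg_df.assign(
            target_id=seg_df["subject_id"] + ":" + seg_df["vessel_id"]
        )
        level_wide["segment"] = (_wide(seg_ids, "target_id", SEGMENT_VARS,
                                       "mean_ca_area"), SEGMENT_VARS)
    if "lesion" in config.levels and not les_df.empty:
        level_wide["lesion"] = (_wide(les_df, "lesion_id", LESION_VARS,
                                      "mean_ca_area"), LESION_VARS)
    if "frame" in config.levels:
        level_wide["frame"] = (_wide(frm_df, "frame_id", FRAME_VARS,
                                     "ca_area_cta"), FRAME_VARS)

    for level, (wide, variables) in level_wide.items():
        try:
            tables = agreement_stage(wide, variables, level, config)
        except Exception as exc:  # abort with stage context
            raise RuntimeError(f"agreement stage failed at {level} level: {exc}") from exc
        for name, df in tables.items():
            p = out / f"{name}_{level}.csv"
            df.to_csv(p, index=False)
            written[f"{name}_{level}"] = p
        try:
            reports, curves = model_stage(wide, variables, level, config)
        except Exception as exc:
            raise RuntimeError(f"model stage failed at {level} level: {exc}") from exc
        p = out / f"models_{level}.json"
        _write_json(reports, p)
        written[f"models_{level}"] = p
        if not curves.empty:
            p = out / f"difference_curves_{level}.csv"
            curves.to_csv(p, index=False)
            written[f"difference_curves_{level}"] = p

    # spread-out export for the first segment of interest
    key, nirs_seg, cta_seg = next(dataset.segments())
    for seg, tag in ((nirs_seg, "nirs"), (cta_seg, "cta")):
        plot = build_spreadout(seg)
        p = out / f"spreadout_{tag}.csv"
        spreadout_to_csv(plot, p)
        written[f"spreadout_{tag}"] = p
        if config.make_plots:
            p = out / f"spreadout_{tag}.png"
            render_spreadout(plot, p, title=f"{key[0]} {key[1]} ({tag.upper()})")
            written[f"spreadout_{tag}_png"] = p

    import scipy
    import statsmodels

    manifest = {
        "package": "plaquekit",
        "version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "seed": config.seed,
        "n_pairs": len(dataset),
        "n_segments": len(dataset.segment_keys()),
        "n_lesions": len(les_df) // 2,
        "library_versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "statsmodels": statsmodels.__version__,
        },
        "outputs": {k: str(v.name) for k, v in written.items()},
    }
    p = out / "manifest.json"
    _write_json(manifest, p)
    written["manifest"] = p
    return written
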