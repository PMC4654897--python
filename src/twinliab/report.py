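"""Assembly of publication-shaped tables and the end-to-end pipeline.

report_table2 mirrors the classical twin-study concordance table (pair
counts, percentages and tetrachoric correlation per zygosity/sex stratum);
report_table3 mirrors the biometric-model summary (prevalences,
correlations, model-based case-wise concordance, heritability, components
with CIs, log-likelihood, AIC and the LRT against the saturated model).
run_pipeline drives simulate/load -> cohort -> concordance -> weights ->
fits -> CIF -> age curves and persists everything with a seed and config
hash in each output.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .age import components_by_age, concordance_by_age
from .competing import censoring_weights, estimate_cif
from .concordance import (concordance_rates, model_casewise,
                          pair_contingency, tetrachoric)
from .liability import LiabilityVarianceModel, compare_models, heritability, make_pair_table
from .simulate import default_params, simulate_cohort

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "report_table2", "report_table3", "run_pipeline",
           "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage, cause):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    out_dir: str = "twinliab_run"
    twin_register: str | None = None     # None -> simulate
    event_register: str | None = None
    n_pairs: int = 45_000
    seed: int = 0
    horizon: float = 70.0
    grid: tuple = (40.0, 90.0, 5.0)      # start, stop, step
    models: tuple = ("saturated", "ACE", "ADE", "AE", "CE")
    sex_mode: str = "adjusted"
    weight_cap: float = 20.0
    bootstrap: int = 200
    make_plots: bool = True

    def age_grid(self):
        start, stop, step = self.grid
        return np.arange(start, stop + 1e-9, step)

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def report_table2(cohort: pd.DataFrame, horizon_age=None) -> pd.DataFrame:
    """Concordance counts, percentages and tetrachoric rho per stratum."""
    rows = []
    for stratum in ("MZM", "DZM", "MZF", "DZF", "OSDZ"):
        tab = pair_contingency(cohort, stratum, horizon_age=horizon_age)
        rates = (concordance_rates(tab) if tab.total
                 else {"pairwise": None, "probandwise": None})
        est = tetrachoric(tab) if tab.total else None
        total = max(tab.total, 1)
        rows.append({
            "stratum": stratum,
            "concordant_affected": tab.n_cc,
            "concordant_affected_pct": round(100 * tab.n_cc / total, 1),
            "discordant": tab.n_cd,
            "discordant_pct": round(100 * tab.n_cd / total, 1),
            "concordant_unaffected": tab.n_dd,
            "concordant_unaffected_pct": round(100 * tab.n_dd / total, 1),
            "total_pairs": tab.total,
            "prevalence": tab.prevalence if tab.total else np.nan,
            "pairwise": rates["pairwise"],
            "probandwise": rates["probandwise"],
            "rho": (est.rho_ if est is not None and not est.boundary_ else np.nan),
            "rho_lo": (est.ci95_[0] if est is not None and est.ci95_ else np.nan),
            "rho_hi": (est.ci95_[1] if est is not None and est.ci95_ else np.nan),
        })
    return pd.DataFrame(rows)


def _fit_block(pairs, sex_mode, sex, models):
    fits = {}
    for m in models:
        fits[m] = LiabilityVarianceModel(model=m, sex_mode=sex_mode, sex=sex).fit(pairs)
    return fits


def report_table3(cohort: pd.DataFrame, horizon: float = 70.0,
                  models=("saturated", "ACE", "ADE", "AE", "CE"),
                  weight_cap: float = 20.0) -> pd.DataFrame:
    """Biometric-model summary rows for men, women and sex-adjusted blocks."""
    w = censoring_weights(cohort, horizon, cap=weight_cap)
    pairs = make_pair_table(cohort, weighted_outcomes=w)

    # weighted observed prevalence per zygosity class for display
    def observed_q(sub):
        sw = sub["w"].sum()
        return float((sub["w"] * (sub["y1"] + sub["y2"])).sum() / (2 * sw)) if sw else np.nan

    rows = []
    for block, (sex_mode, sex) in {"men": ("stratified", "M"),
                                   "women": ("stratified", "F"),
                                   "sex_adjusted": ("adjusted", None)}.items():
        try:
            fits = _fit_block(pairs, sex_mode, sex, models)
        except ValueError as e:
            logger.warning("skipping block %s: %s", block, e)
            continue
        sat = fits.get("saturated")
        if sex_mode == "stratified":
            sub = pairs[(pairs["zygosity"] != "DZOS") & (pairs["sex1"] == sex)]
        else:
            sub = pairs
        q_mz = observed_q(sub[sub["zygosity"] == "MZ"])
        q_dz = observed_q(sub[sub["zygosity"] != "MZ"])
        for m, fit in fits.items():
            rmz, rdz = fit.implied_rmz_, fit.implied_rdz_
            row = {
                "block": block, "model": m,
                "prevalence_MZ": q_mz, "prevalence_DZ": q_dz,
                "rMZ": rmz, "rDZ": rdz,
                "MZ_casewise": (model_casewise(rmz, q_mz)
                                if np.isfinite(q_mz) and 0 < q_mz < 1 else np.nan),
                "DZ_casewise": (model_casewise(rdz, q_dz)
                                if np.isfinite(q_dz) and 0 < q_dz < 1 else np.nan),
                "heritability": heritability(fit)["h2"] if fit.converged_ else np.nan,
                "loglik": fit.loglik_, "aic": fit.aic_,
                "n_free_params": fit.n_free_params_,
                "converged": fit.converged_,
            }
            for comp in ("a2", "d2", "c2", "e2"):
                if fit.components_ is not None:
                    row[comp] = fit.components_[comp]
                    row[f"{comp}_lo"], row[f"{comp}_hi"] = fit.ci95_[comp]
                else:
                    row[comp] = row[f"{comp}_lo"] = row[f"{comp}_hi"] = np.nan
            if (m != "saturated" and sat is not None and sat.converged_
                    and fit.n_free_params_ < sat.n_free_params_):
                lrt = compare_models(fit, sat)
                row.update(chi2=lrt["chi2"], df=lrt["df"], p=lrt["p"])
            else:
                row.update(chi2=np.nan, df=np.nan, p=np.nan)
            rows.append(row)
    return pd.DataFrame(rows)


def _write_tsv(df: pd.DataFrame, path: Path, header_meta: dict):
    with open(path, "w") as fh:
        for k, v in header_meta.items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, sep="\t", index=False)


def run_pipeline(config: RunConfig) -> Path:
    """Execute the full analysis and persist all artifacts.

    Any stage failure raises PipelineError naming the stage; outputs of the
    stages already completed remain on disk next to the run log.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta = {"seed": config.seed, "config_hash": config.config_hash(),
            "version": __version__}
    log = {"config": dataclasses.asdict(config), **meta,
           "stages": [], "warnings": []}
    stage = "setup"

    def run_stage(name, fn):
        nonlocal stage
        stage = name
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as e:  # noqa: BLE001 - report the failing stage
            log["stages"].append({"stage": name, "ok": False, "error": str(e)})
            (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
            raise PipelineError(name, e) from e
        log["stages"].append({"stage": name,
                              "seconds": round(time.perf_counter() - t0, 2),
                              "ok": True})
        return result

    def stage_cohort():
        if config.twin_register is not None:
            from .io import build_analysis_cohort, load_event_register, load_twin_register
            twins = load_twin_register(config.twin_register)
            events = load_event_register(config.event_register)
            cohort, ledger = build_analysis_cohort(twins, events)
        else:
            params = default_params(n_pairs=config.n_pairs, seed=config.seed)
            cohort = simulate_cohort(params)
            ledger = {"input_individuals": int(len(cohort)),
                      "cohort_individuals": int(len(cohort))}
        return cohort, ledger

    cohort, ledger = run_stage("cohort", stage_cohort)
    log["ledger"] = ledger
    cohort_out = cohort.copy()
    run_stage("write_cohort", lambda: _write_tsv(cohort_out, out / "cohort.tsv", meta))

    t2 = run_stage("table2", lambda: report_table2(cohort))
    run_stage("write_table2", lambda: _write_tsv(t2, out / "table2.tsv", meta))

    t3 = run_stage("table3", lambda: report_table3(
        cohort, horizon=config.horizon, models=config.models,
        weight_cap=config.weight_cap))
    log["convergence"] = {f"{r.block}/{r.model}": bool(r.converged)
                          for r in t3.itertuples()}
    run_stage("write_table3", lambda: _write_tsv(t3, out / "table3.tsv", meta))

    w = run_stage("weights", lambda: censoring_weights(
        cohort, config.horizon, cap=config.weight_cap))
    run_stage("write_weights", lambda: _write_tsv(w, out / "weights.tsv", meta))

    cif = run_stage("cif", lambda: estimate_cif(cohort, by_sex=True))
    def cif_frame():
        parts = []
        for sex, curve in cif.items():
            parts.append(pd.DataFrame({
                "sex": sex, "age": curve.age_grid,
                "cif_case": curve.cif["case"], "se_case": curve.se["case"],
                "cif_death": curve.cif["death"], "se_death": curve.se["death"],
                "n_at_risk": curve.n_at_risk}))
        return pd.concat(parts, ignore_index=True)
    cif_df = run_stage("cif_frame", cif_frame)
    run_stage("write_cif", lambda: _write_tsv(cif_df, out / "cif.tsv", meta))

    grid = config.age_grid()
    conc = run_stage("concordance_by_age", lambda: concordance_by_age(
        cohort, grid, n_boot=config.bootstrap, random_state=config.seed,
        cap=config.weight_cap))
    comp = run_stage("components_by_age", lambda: components_by_age(
        cohort, grid, model="ACE", cap=config.weight_cap))
    conc_df = pd.concat([c.as_frame() for c in conc.values()], ignore_index=True)
    comp_df = pd.concat([c.as_frame() for c in comp.values()], ignore_index=True)
    run_stage("write_age_curves", lambda: (
        _write_tsv(conc_df, out / "age_concordance.tsv", meta),
        _write_tsv(comp_df, out / "age_components.tsv", meta)))

    if config.make_plots:
        run_stage("plots", lambda: _make_plots(out, cif, conc, comp))

    stage = "finalize"
    (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return out


def _make_plots(out: Path, cif, conc, comp):
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for sex, color in (("M", "tab:red"), ("F", "black")):
        ax.step(cif[sex].age_grid, cif[sex].cif["case"], where="post",
                color=color, label=f"{sex} case")
    ax.set_xlabel("age (years)")
    ax.set_ylabel("cumulative incidence")
    ax.legend()
    fig.savefig(out / "cif.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    for lab, curve in conc.items():
        ax.plot(curve.ages, curve.value, marker="o", label=lab)
        ax.fill_between(curve.ages, curve.lo, curve.hi, alpha=0.2)
    ax.set_xlabel("age (years)")
    ax.set_ylabel("proband-wise concordance")
    ax.legend()
    fig.savefig(out / "concordance_age.png", dpi=120, bbox_inches="tight")
    plt.close(fig)

    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"a2": "tab:red", "c2": "tab:blue", "e2": "tab:green", "h2": "gray"}
    for lab, curve in comp.items():
        ax.plot(curve.ages, curve.value, marker="o", label=lab,
                color=colors.get(lab))
        ax.fill_between(curve.ages, curve.lo, curve.hi, alpha=0.15,
                        color=colors.get(lab))
    ax.set_xlabel("age (years)")
    ax.set_ylabel("proportion of liability variance")
    ax.set_ylim(0, 1)
    ax.legend()
    fig.savefig(out / "components_age.png", dpi=120, bbox_inches="tight")
    plt.close(fig)
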