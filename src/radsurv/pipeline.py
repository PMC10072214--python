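"""End-to-end pipeline: simulate -> extract -> stability -> reduce -> model.

One :func:`run_pipeline` call generates a synthetic cohort, extracts
radiomic (CT) and dosiomic (dose) feature tables, filters them by the
perturbation ICC test, reduces each stable pool to five principal
components, fits the six-model Cox suite and writes every intermediate
table plus a run manifest (config hash, seeds, per-file checksums) so
the run can be replayed bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time as _time
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .features import extract_cohort, feature_names, write_manifest
from .phantom import generate_cohort
from .reduction import fit_pca, screen_features, youden_cutoff
from .stability import stability_filter, stability_report
from .survival import (
    MODEL_NAMES,
    CoxFit,
    SurvivalData,
    build_model_suite,
    km_estimate,
    logrank_test,
)

__all__ = ["run_pipeline", "PipelineResult"]


def _sha(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _write_csv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, index=index, float_format="%.10g")


def _model_report(name: str, fit: CoxFit) -> dict:
    return {
        "model": name,
        "covariates": fit.covariates,
        "coef": {c: float(fit.coef[c]) for c in fit.covariates},
        "HR": {c: float(fit.hr[c]) for c in fit.covariates},
        "HR_95CI": {
            c: [float(fit.hr_ci_lower[c]), float(fit.hr_ci_upper[c])]
            for c in fit.covariates
        },
        "z": {c: float(fit.z[c]) for c in fit.covariates},
        "p": {c: float(fit.p[c]) for c in fit.covariates},
        "log_partial_likelihood": fit.log_likelihood,
        "n_params": fit.n_params,
        "AIC": fit.aic,
        "c_index": fit.c_index,
        "c_index_95CI": list(fit.c_index_ci_95) if fit.c_index_ci_95 else None,
    }


def _markdown_table(fits: dict[str, CoxFit]) -> str:
    lines = ["| Model | Covariate | HR (95% CI) | z | p |", "|---|---|---|---|---|"]
    for name, fit in fits.items():
        header = f"**{name}** (AIC {fit.aic:.2f}; C-index {fit.c_index:.3f})"
        for i, c in enumerate(fit.covariates):
            lines.append(
                f"| {header if i == 0 else ''} | {c} | "
                f"{fit.hr[c]:.2f} ({fit.hr_ci_lower[c]:.2f}-{fit.hr_ci_upper[c]:.2f}) | "
                f"{fit.z[c]:.2f} | {fit.p[c]:.3g} |"
            )
    return "\n".join(lines) + "\n"


class PipelineResult(dict):
    """Dict of stage outputs with attribute access for the common ones."""

    @property
    def fits(self) -> dict[str, CoxFit]:
        return self["fits"]

    @property
    def manifest(self) -> dict:
        return self["manifest"]


def run_pipeline(config: PipelineConfig, out_dir: str | Path | None = None) -> PipelineResult:
    """Execute all stages for both modalities; write outputs under out_dir."""
    t0 = _time.time()
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    warnings_log: list[str] = []
    stage = "simulate"
    try:
        patients, cohort = generate_cohort(config.n_patients, config.phantom, config.hazard)
        outcomes = SurvivalData(
            cohort["time_months"].to_numpy(), cohort["event"].to_numpy()
        )

        stage = "extract"
        ct_inputs = [(p.patient_id, p.ct, p.voi) for p in patients]
        dose_inputs = [(p.patient_id, p.dose, p.voi) for p in patients]
        radiomic = extract_cohort(ct_inputs, config.disc_ct, config.filter_bank)
        dosiomic = extract_cohort(dose_inputs, config.disc_dose, config.filter_bank)

        stage = "stability"
        thresholds = (config.thresholds.icc1, config.thresholds.icc2)
        reports = {}
        stable = {}
        for modality, table, inputs, disc in (
            ("radiomic", radiomic, ct_inputs, config.disc_ct),
            ("dosiomic", dosiomic, dose_inputs, config.disc_dose),
        ):
            rep = stability_report(
                inputs, table, modality, config.perturbation, disc,
                config.filter_bank, config.icc1_formula,
            )
            reports[modality] = rep
            stable[modality] = stability_filter(
                rep, modality, config.perturbation, thresholds
            )

        stage = "reduce"
        pcs = {}
        screens = {}
        for modality, table, prefix in (
            ("radiomic", radiomic, "RPC"),
            ("dosiomic", dosiomic, "DPC"),
        ):
            pool = table[stable[modality]]
            if config.screen_before_pca:
                with warnings.catch_warnings(record=True) as wlog:
                    warnings.simplefilter("always")
                    screen = screen_features(pool, outcomes, config.thresholds.alpha)
                warnings_log += [str(w.message) for w in wlog]
                screens[modality] = screen
                pool = pool[screen.selected]
            with warnings.catch_warnings(record=True) as wlog:
                warnings.simplefilter("always")
                pcs[modality] = fit_pca(pool, config.thresholds.n_components, prefix)
            warnings_log += [str(w.message) for w in wlog]

        stage = "model"
        clinical = cohort.set_index("patient_id")[
            ["gender", "age", "stage_ivb", "peripheral_invasion"]
        ]
        with warnings.catch_warnings(record=True) as wlog:
            warnings.simplefilter("always")
            fits = build_model_suite(
                pcs["radiomic"].scores,
                pcs["dosiomic"].scores,
                clinical,
                outcomes,
                ci_boot=200,
                seed=config.seed,
            )
        warnings_log += [str(w.message) for w in wlog]

        # KM export: each significant PC dichotomized at its Youden cutoff
        km_rows = []
        for modality in ("radiomic", "dosiomic"):
            scores = pcs[modality].scores
            for pc in fits[modality].significant:
                cut = youden_cutoff(scores[pc].to_numpy(), outcomes.event)
                hi = scores[pc].to_numpy() > cut
                chi2, p = logrank_test(outcomes.subset(hi), outcomes.subset(~hi))
                for label, idx in (("high", hi), ("low", ~hi)):
                    curve = km_estimate(outcomes.subset(idx))
                    df = curve.frame()
                    df.insert(0, "group", f"{pc}_{label}")
                    df["logrank_chi2"] = chi2
                    df["logrank_p"] = p
                    km_rows.append(df)
        km_table = pd.concat(km_rows, ignore_index=True) if km_rows else pd.DataFrame()
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    result = PipelineResult(
        cohort=cohort,
        radiomic=radiomic,
        dosiomic=dosiomic,
        stability=reports,
        stable=stable,
        screens=screens,
        pcs=pcs,
        fits=fits,
        km=km_table,
    )

    manifest = {
        "config": config.to_dict(),
        "config_hash": hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16],
        "seed": config.seed,
        "n_patients": config.n_patients,
        "n_features_per_modality": len(feature_names(config.filter_bank)),
        "n_stable": {m: len(v) for m, v in stable.items()},
        "warnings": warnings_log,
        "runtime_s": round(_time.time() - t0, 2),
        "outputs": {},
    }

    if out is not None:
        _write_csv(cohort, out / "cohort.csv", index=False)
        _write_csv(radiomic, out / "features_radiomic.csv")
        _write_csv(dosiomic, out / "features_dosiomic.csv")
        for m in ("radiomic", "dosiomic"):
            rep = reports[m].copy()
            rep["pass"] = rep["feature"].isin(stable[m])
            _write_csv(rep, out / f"stability_{m}.csv", index=False)
            _write_csv(pcs[m].scores, out / f"pc_scores_{m}.csv")
            (out / f"pc_model_{m}.json").write_text(
                json.dumps(
                    {
                        "features": pcs[m].feature_names,
                        "means": pcs[m].means.tolist(),
                        "scales": pcs[m].scales.tolist(),
                        "loadings": pcs[m].loadings.tolist(),
                        "explained_variance_ratio": pcs[m].explained_variance_ratio.tolist(),
                    },
                    indent=2,
                )
            )
        (out / "stability_summary.json").write_text(
            json.dumps(
                {
                    "icc1_formula": config.icc1_formula,
                    "thresholds": {"icc1": config.thresholds.icc1, "icc2": config.thresholds.icc2},
                    "n_stable": manifest["n_stable"],
                    "n_total": manifest["n_features_per_modality"],
                },
                indent=2,
            )
        )
        (out / "models.json").write_text(
            json.dumps([_model_report(n, fits[n]) for n in MODEL_NAMES], indent=2)
        )
        (out / "models.md").write_text(_markdown_table(fits))
        if len(km_table):
            _write_csv(km_table, out / "km_curves.csv", index=False)
        write_manifest(out / "feature_manifest.json", config.disc_ct, config.filter_bank)
        manifest["outputs"] = {
            p.name: _sha(p) for p in sorted(out.iterdir()) if p.suffix in (".csv", ".json", ".md")
        }
        (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))

    result["manifest"] = manifest
    return result
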