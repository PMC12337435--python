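"""End-to-end co-aggregation study: from pedigree + phenotype panel to the
full grid of recurrence risk ratios and familial correlations with FDR
control.

For every ordered (outcome, relative-phenotype) pair and relative degree a
logistic prevalence model is fitted with covariates
[intercept, exposure, age, age^2, sex, n relatives with data], clustered on
family. Average adjusted predictions over the full sample and over the
exposed subgroup give the general-population and exposed prevalences;
first-degree models yield lambda_R, and the (degree x direction) quartet of
models yields the familial correlation of the unordered pair.
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .coaggregation import recurrence_risk_ratio
from .inference import ResultsTable, assemble_results
from .liability import EXACT, RfComponent, estimate_familial_correlation, liability_params
from .pedigree import FEMALE, FIRST, MALE, Pedigree, SECOND
from .phenotype import PhenotypePanel, summarize
from .prevalence import FitError, PrevalenceEstimate, average_adjusted_prediction, fit_prevalence_model

logger = logging.getLogger(__name__)

MODEL_COLUMNS = ["intercept", "exposure", "age", "age_sq", "sex", "n_relatives"]

LAMBDA_SCHEMA = [
    "outcome", "relative_phenotype", "degree", "n_pop", "n_exposed",
    "K_pop", "se_pop", "K_exposed", "se_exposed",
    "lambda", "se_lambda", "lower95", "p_one_sided",
]


@dataclass
class PairModel:
    """One fitted (outcome, relative phenotype, degree) prevalence model."""

    outcome: str
    relative_phenotype: str
    degree: str
    pop: PrevalenceEstimate
    exposed: PrevalenceEstimate | None
    n_dropped: int


class StudyContext:
    """Aligned arrays shared by every model of one study run."""

    def __init__(self, ped: Pedigree, panel: PhenotypePanel):
        self.ped = ped
        self.panel = panel
        self.n_fam = ped.n_families
        self.family = ped.family_id
        sex = ped.sex_series()
        self.sex01 = np.where(sex == FEMALE, 1.0, np.where(sex == MALE, 0.0, np.nan))
        status = panel.status.reindex(ped.iids)
        self.status = {ph: status[ph].fillna(-1).to_numpy(dtype=np.int8) for ph in panel.phenotypes}
        age = panel.age.reindex(ped.iids)
        self.age = {ph: age[ph].to_numpy(dtype=float) for ph in panel.phenotypes}
        self._warm: dict[tuple, np.ndarray] = {}
        self._exposures: dict[tuple, tuple[np.ndarray, np.ndarray]] = {}
        self._design: dict[tuple, tuple] = {}

    def _exposure_arrays(self, relative_phenotype: str, degree: str) -> tuple[np.ndarray, np.ndarray]:
        """(exposure indicator, n relatives with data), cached per run."""
        key = (relative_phenotype, degree)
        cached = self._exposures.get(key)
        if cached is None:
            i_idx, j_idx = self.ped.degree_pair_indices(degree)
            st = self.status[relative_phenotype]
            exp_acc = np.zeros(len(self.ped), dtype=np.int64)
            nrel = np.zeros(len(self.ped), dtype=np.int64)
            if len(i_idx):
                np.add.at(exp_acc, i_idx, (st[j_idx] == 1).astype(np.int64))
                np.add.at(nrel, i_idx, (st[j_idx] >= 0).astype(np.int64))
            cached = ((exp_acc > 0).astype(float), nrel.astype(float))
            self._exposures[key] = cached
        return cached

    def _outcome_design(self, outcome: str) -> tuple:
        """Per-outcome row mask, outcome vector, base design matrix and family
        labels (exposure and relative-count columns filled per model)."""
        cached = self._design.get(outcome)
        if cached is None:
            y_all = self.status[outcome]
            age_all = self.age[outcome]
            keep = (y_all >= 0) & np.isfinite(self.sex01) & np.isfinite(age_all)
            n_dropped = int((y_all >= 0).sum() - keep.sum())
            y = y_all[keep].astype(float)
            age = age_all[keep]
            X = np.zeros((int(keep.sum()), len(MODEL_COLUMNS)))
            X[:, 0] = 1.0
            X[:, 2] = age
            X[:, 3] = age**2
            X[:, 4] = self.sex01[keep]
            center = X.mean(axis=0)
            scale = X.std(axis=0)
            center[0], scale[0] = 0.0, 1.0
            center[1], scale[1] = 0.0, 1.0  # placeholders; filled per model
            center[5], scale[5] = 0.0, 1.0
            Xs = (X - center) / scale  # cols 1 and 5 are zeros for now
            fams = self.family[keep]
            labels, cindex = np.unique(fams, return_inverse=True)
            starts = None
            if len(labels) > 1 and np.all(np.diff(cindex) >= 0):
                starts = np.searchsorted(cindex, np.arange(len(labels)))
            clusters = (labels, cindex, starts)
            cached = (keep, y, X, Xs, fams, n_dropped, center, scale, clusters)
            self._design[outcome] = cached
        return cached

    def fit_pair_model(
        self,
        outcome: str,
        relative_phenotype: str,
        degree: str,
        aap_mode: str = "observed",
    ) -> PairModel:
        """Fit the prevalence model for one (outcome, relative, degree) cell
        and return its population and exposed-subgroup AAPs."""
        exp_all, nrel_all = self._exposure_arrays(relative_phenotype, degree)
        keep, y, X_base, Xs_base, fams, n_dropped, center, scale, clusters = self._outcome_design(outcome)
        if n_dropped:
            logger.info("%s|%s (%s): dropped %d rows with missing covariates", outcome, relative_phenotype, degree, n_dropped)
        exposure = exp_all[keep]
        nrel = nrel_all[keep]
        center, scale = center.copy(), scale.copy()
        Xs = Xs_base.copy()
        n = len(Xs)
        for j, col in ((1, exposure), (5, nrel)):
            center[j] = col.mean()
            scale[j] = np.sqrt(max((col @ col) / n - center[j] ** 2, 0.0))
            if scale[j] > 1e-12:
                Xs[:, j] = (col - center[j]) / scale[j]
        key = (outcome, relative_phenotype, degree)
        fit = fit_prevalence_model(
            y, Xs, fams, names=MODEL_COLUMNS, beta0=self._warm.get(key),
            standardization=(center, scale), clusters=clusters, prestandardized=True,
        )
        self._warm[key] = fit.beta

        pop = average_adjusted_prediction(fit, subset="population")
        exposed_mask = exposure == 1.0
        exposed: PrevalenceEstimate | None = None
        if exposed_mask.any():
            if aap_mode == "counterfactual":
                X = X_base.copy()
                X[:, 1] = exposure
                X[:, 5] = nrel
                exposed = average_adjusted_prediction(
                    fit, X, None, subset="exposed", counterfactual_exposure=1, exposure_col=1
                )
                exposed.n = int(exposed_mask.sum())
            else:
                exposed = average_adjusted_prediction(fit, subset_mask=exposed_mask, subset="exposed")
        for est in (pop, exposed):
            if est is not None and est.influence is not None:
                full = np.zeros(self.n_fam)
                full[fit.cluster_labels] = est.influence
                est.influence = full
        return PairModel(outcome, relative_phenotype, degree, pop, exposed, n_dropped)


def _missing_lambda_row(outcome: str, relative: str, degree: str, reason: str) -> dict:
    warnings.warn(f"lambda {outcome} | relative {relative} ({degree}): {reason}; emitting missing row", stacklevel=3)
    row = {c: np.nan for c in LAMBDA_SCHEMA}
    row.update(outcome=outcome, relative_phenotype=relative, degree=degree)
    return row


def run_grid(
    ped: Pedigree,
    panel: PhenotypePanel,
    focal: list[str],
    diseases: list[str],
    q: float = 0.05,
    rf_mode: str = EXACT,
    aap_mode: str = "observed",
    bh_family: str = "pooled",
    log_scale_ci: bool = False,
    context: StudyContext | None = None,
) -> tuple[ResultsTable, dict]:
    """Run the full focal x disease grid and BH-adjust across all tests.

    Returns the assembled :class:`ResultsTable` and a manifest dictionary
    with per-model sample sizes. A prefitted ``context`` may be passed to
    reuse alignment work (and Newton warm starts) across repeated runs on the
    same pedigree, as in replicate simulations.
    """
    ctx = context if context is not None else StudyContext(ped, panel)
    overlap = set(focal) & set(diseases)
    if overlap:
        raise ValueError(f"phenotypes cannot be both focal and disease: {sorted(overlap)}")

    models: dict[tuple, PairModel | None] = {}
    model_info = []
    for a in focal:
        for b in diseases:
            for outcome, relative in ((a, b), (b, a)):
                for degree in (FIRST, SECOND):
                    key = (outcome, relative, degree)
                    try:
                        pm = ctx.fit_pair_model(outcome, relative, degree, aap_mode=aap_mode)
                    except (FitError, ValueError) as err:
                        warnings.warn(f"model {key} failed: {err}", stacklevel=2)
                        pm = None
                    models[key] = pm
                    if pm is not None:
                        model_info.append(
                            {
                                "outcome": outcome,
                                "relative_phenotype": relative,
                                "degree": degree,
                                "n": pm.pop.n,
                                "n_exposed": 0 if pm.exposed is None else pm.exposed.n,
                                "n_dropped": pm.n_dropped,
                            }
                        )

    lambda_rows = []
    for a in focal:
        for b in diseases:
            for outcome, relative in ((a, b), (b, a)):
                pm = models[(outcome, relative, FIRST)]
                if pm is None:
                    lambda_rows.append(_missing_lambda_row(outcome, relative, FIRST, "model failed"))
                    continue
                if pm.exposed is None:
                    lambda_rows.append(_missing_lambda_row(outcome, relative, FIRST, "no exposed individuals"))
                    continue
                lam = recurrence_risk_ratio(
                    pm.exposed, pm.pop, pair=(outcome, relative), degree=FIRST, log_scale=log_scale_ci
                )
                lambda_rows.append(
                    {
                        "outcome": outcome,
                        "relative_phenotype": relative,
                        "degree": FIRST,
                        "n_pop": pm.pop.n,
                        "n_exposed": pm.exposed.n,
                        "K_pop": pm.pop.K_hat,
                        "se_pop": pm.pop.se,
                        "K_exposed": pm.exposed.K_hat,
                        "se_exposed": pm.exposed.se,
                        "lambda": lam.lambda_hat,
                        "se_lambda": lam.se,
                        "lower95": lam.lower95,
                        "p_one_sided": lam.p_one_sided,
                    }
                )

    rf_rows = []
    for a in focal:
        for b in diseases:
            components = []
            for degree in (FIRST, SECOND):
                for outcome, relative, tag in ((a, b, "A|B"), (b, a, "B|A")):
                    pm = models[(outcome, relative, degree)]
                    pm_rev = models[(relative, outcome, degree)]
                    if pm is None or pm.exposed is None or pm_rev is None:
                        continue
                    components.append(
                        RfComponent(
                            degree=degree,
                            direction=tag,
                            prevalence=pm.exposed,
                            outcome_params=liability_params(pm.pop.K_hat),
                            relative_params=liability_params(pm_rev.pop.K_hat),
                        )
                    )
            row = {"phenotype_A": a, "phenotype_B": b, "mode": rf_mode,
                   "rf": np.nan, "se": np.nan, "lower95": np.nan, "p_one_sided": np.nan}
            for degree in (FIRST, SECOND):
                for tag in ("A|B", "B|A"):
                    suffix = f"{degree}_{tag.replace('|', '')}"
                    row[f"rf_{suffix}"] = np.nan
                    row[f"se_{suffix}"] = np.nan
            est = estimate_familial_correlation(components, mode=rf_mode) if components else None
            if est is not None:
                row.update(rf=est.rf, se=est.se, lower95=est.lower95, p_one_sided=est.p_one_sided)
                for comp in est.components:
                    suffix = f"{comp.degree}_{comp.direction.replace('|', '')}"
                    row[f"rf_{suffix}"] = comp.rf
                    row[f"se_{suffix}"] = comp.se
            else:
                warnings.warn(f"familial correlation {a}-{b}: no usable components", stacklevel=2)
            rf_rows.append(row)

    results = assemble_results(
        pd.DataFrame(lambda_rows, columns=LAMBDA_SCHEMA),
        pd.DataFrame(rf_rows),
        q=q,
        family=bh_family,
    )
    manifest = {
        "version": __version__,
        "n_individuals": len(ped),
        "n_families": ped.n_families,
        "focal": list(focal),
        "diseases": list(diseases),
        "q": q,
        "rf_mode": rf_mode,
        "aap_mode": aap_mode,
        "n_lambda_tests": results.n_lambda,
        "n_rf_tests": results.n_rf,
        "n_tests": results.n_lambda + results.n_rf,
        "models": model_info,
    }
    return results, manifest


def run_study(config_path: str | Path) -> dict:
    """File-based pipeline entry point: read config, pedigree and phenotype
    TSV, run the grid, write results TSVs and a manifest. Returns paths."""
    config_path = Path(config_path)
    with open(config_path) as fh:
        cfg = yaml.safe_load(fh)
    for required in ("pedigree", "phenotypes", "wave_order", "focal", "diseases"):
        if required not in cfg:
            raise ValueError(f"{config_path}: missing config key {required!r}")
    base = config_path.parent
    out_dir = Path(cfg.get("output_dir", "results"))
    if not out_dir.is_absolute():
        out_dir = base / out_dir
    out_dir.mkdir(parents=True, exist_ok=True)

    ped = Pedigree.from_ped_file(_resolve(base, cfg["pedigree"]))
    records = PhenotypePanel.read_assessments_tsv(_resolve(base, cfg["phenotypes"]))
    panel = PhenotypePanel.from_records(records, cfg["wave_order"])
    for name, comps in (cfg.get("composites") or {}).items():
        panel = panel.add_composite(name, comps)
    if cfg.get("exclusions"):
        panel = panel.apply_exclusions(cfg["exclusions"])

    results, manifest = run_grid(
        ped,
        panel,
        focal=cfg["focal"],
        diseases=cfg["diseases"],
        q=float(cfg.get("q", 0.05)),
        rf_mode=cfg.get("rf_mode", EXACT),
        aap_mode=cfg.get("aap_mode", "observed"),
        bh_family=cfg.get("bh_family", "pooled"),
    )

    table = results.table
    lam = table[table["statistic"] == "lambda"].dropna(axis=1, how="all")
    rf = table[table["statistic"] == "rf"].dropna(axis=1, how="all")
    paths = {
        "results": out_dir / "results.tsv",
        "lambda": out_dir / "lambda.tsv",
        "rf": out_dir / "rf.tsv",
        "manifest": out_dir / "manifest.json",
        "summary": out_dir / "summary.tsv",
    }
    table.to_csv(paths["results"], sep="\t", index=False)
    lam.to_csv(paths["lambda"], sep="\t", index=False)
    rf.to_csv(paths["rf"], sep="\t", index=False)
    summarize(panel, ped).to_csv(paths["summary"], sep="\t", index=False)
    manifest["config_sha256"] = hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()
    manifest["config"] = str(config_path)
    manifest["seed"] = cfg.get("seed")
    with open(paths["manifest"], "w") as fh:
        json.dump(manifest, fh, indent=2)
    logger.info("wrote %d test results to %s", manifest["n_tests"], out_dir)
    return {k: str(v) for k, v in paths.items()}


def _resolve(base: Path, p) -> Path:
    p = Path(p)
    return p if p.is_absolute() else base / p
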