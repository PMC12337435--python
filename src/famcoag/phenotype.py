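"""Lifetime phenotype derivation from multi-wave assessment records.

Participants assessed at several waves are lifetime cases if they fulfil a
case definition at any wave, controls if they fulfil it at no non-missing
wave, and missing only if every wave is missing. The analysis age is the age
at which a case first satisfied the definition, and for controls the last age
with relevant data. Composite phenotypes (any-of over components) follow the
same logic and do not require complete component data to call a control.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

CASE, CONTROL, MISSING = "case", "control", "missing"
_CODE = {CASE: 1, CONTROL: 0, MISSING: -1}
_STATUS = {1: CASE, 0: CONTROL, -1: MISSING}


class PhenotypeError(ValueError):
    pass


@dataclass(frozen=True)
class AssessmentRecord:
    """One wave-level assessment of one phenotype for one individual."""

    iid: str
    phenotype: str
    wave: str
    status: str  # case / control / missing
    age: float | None = None

    def __post_init__(self):
        if self.status not in _CODE:
            raise PhenotypeError(f"invalid status {self.status!r}")
        if self.status != MISSING and self.age is None:
            raise PhenotypeError(f"age required for non-missing status ({self.iid}, {self.phenotype}, {self.wave})")
        if self.age is not None and not (0 <= self.age <= 120):
            raise PhenotypeError(f"implausible age {self.age}")


def aggregate_lifetime(records: Sequence[AssessmentRecord]) -> str:
    """Lifetime status for one individual-phenotype: case if any wave is a
    case, else control if any wave is a control, else missing."""
    statuses = {r.status for r in records}
    if CASE in statuses:
        return CASE
    if CONTROL in statuses:
        return CONTROL
    return MISSING


def composite_phenotype(component_statuses: Sequence[str]) -> str:
    """Any-of composite over component lifetime statuses; complete data on
    all components is not required to be a control."""
    if not component_statuses:
        raise PhenotypeError("composite requires at least one component")
    if CASE in component_statuses:
        return CASE
    if CONTROL in component_statuses:
        return CONTROL
    return MISSING


def assign_analysis_age(records: Sequence[AssessmentRecord], lifetime_status: str, wave_order: Sequence[str]) -> float | None:
    """Case: age at the earliest wave fulfilling the definition. Control: age
    at the latest wave with non-missing data. Missing: None."""
    order = {w: k for k, w in enumerate(wave_order)}
    recs = sorted((r for r in records if r.wave in order), key=lambda r: order[r.wave])
    if lifetime_status == MISSING:
        return None
    if lifetime_status == CASE:
        for r in recs:
            if r.status == CASE:
                return r.age
        raise PhenotypeError("lifetime case but no wave-level case record")
    for r in reversed(recs):
        if r.status != MISSING:
            return r.age
    raise PhenotypeError("lifetime control but no non-missing wave record")


class PhenotypePanel:
    """Per (individual, phenotype) lifetime status and analysis age.

    ``status`` is an int8 DataFrame (index iid, one column per phenotype,
    values 1=case, 0=control, -1=missing) and ``age`` a float DataFrame of the
    same shape (NaN where status is missing).
    """

    def __init__(self, status: pd.DataFrame, age: pd.DataFrame):
        if not status.index.equals(age.index) or list(status.columns) != list(age.columns):
            raise PhenotypeError("status and age frames must be aligned")
        self.status = status.astype(np.int8)
        self.age = age.astype(float)
        bad = (self.status.to_numpy() == -1) & ~np.isnan(self.age.to_numpy())
        if bad.any():
            raise PhenotypeError("age present where lifetime status is missing")

    # -- construction --------------------------------------------------------

    @classmethod
    def from_records(cls, records: pd.DataFrame, wave_order: Sequence[str]) -> "PhenotypePanel":
        """Aggregate a long wave-level table (iid, phenotype, wave, status, age).

        ``status`` holds 1/0/NA. Duplicate (iid, phenotype, wave) rows are an
        error. Wave ordering comes from ``wave_order``, not label sort order.
        """
        df = records.copy()
        required = {"iid", "phenotype", "wave", "status", "age"}
        if not required.issubset(df.columns):
            raise PhenotypeError(f"records need columns {sorted(required)}")
        unknown_waves = set(df["wave"].unique()) - set(wave_order)
        if unknown_waves:
            raise PhenotypeError(f"waves not in wave_order: {sorted(unknown_waves)}")
        if df.duplicated(["iid", "phenotype", "wave"]).any():
            dup = df[df.duplicated(["iid", "phenotype", "wave"])].iloc[0]
            raise PhenotypeError(f"duplicate assessment row ({dup['iid']}, {dup['phenotype']}, {dup['wave']})")

        code = df["status"].astype(float)
        df["_code"] = np.where(np.isnan(code), -1, code).astype(np.int8)
        if not set(np.unique(df["_code"])) <= {1, 0, -1}:
            raise PhenotypeError("status must be 1, 0 or NA")
        if (np.isnan(df["age"].to_numpy(dtype=float)) & (df["_code"].to_numpy() >= 0)).any():
            raise PhenotypeError("age required wherever wave status is non-missing")
        df["_order"] = df["wave"].map({w: k for k, w in enumerate(wave_order)})
        df = df.sort_values("_order", kind="stable")

        grp = df.groupby(["iid", "phenotype"], sort=True)
        lifetime = grp["_code"].max()  # 1 > 0 > -1 encodes case > control > missing

        cases = df[df["_code"] == 1].groupby(["iid", "phenotype"], sort=True)["age"].first()
        ctrl = df[df["_code"] >= 0].groupby(["iid", "phenotype"], sort=True)["age"].last()
        age = ctrl.copy()
        age.loc[cases.index] = cases
        age = age.reindex(lifetime.index)
        age[lifetime == -1] = np.nan

        status_wide = lifetime.unstack("phenotype", fill_value=-1).astype(np.int8)
        age_wide = age.unstack("phenotype")
        return cls(status_wide, age_wide.reindex(columns=status_wide.columns))

    @classmethod
    def from_cube(
        cls,
        iids: Sequence[str],
        phenotypes: Sequence[str],
        status_cube: np.ndarray,
        age_cube: np.ndarray,
    ) -> "PhenotypePanel":
        """Vectorized aggregation from (n_individuals, n_phenotypes, n_waves)
        arrays of wave-level status codes (1/0/-1) and ages; waves are already
        in assessment order along the last axis."""
        status_cube = np.asarray(status_cube, dtype=np.int8)
        age_cube = np.asarray(age_cube, dtype=float)
        lifetime = status_cube.max(axis=2).astype(np.int8)

        n, p, w = status_cube.shape
        is_case = status_cube == 1
        nonmiss = status_cube >= 0
        first_case = np.where(is_case.any(axis=2), is_case.argmax(axis=2), 0)
        last_obs = w - 1 - np.where(nonmiss.any(axis=2), nonmiss[:, :, ::-1].argmax(axis=2), 0)
        ii, pp = np.meshgrid(np.arange(n), np.arange(p), indexing="ij")
        age = np.where(
            lifetime == 1,
            age_cube[ii, pp, first_case],
            age_cube[ii, pp, last_obs],
        )
        age = np.where(lifetime == -1, np.nan, age)
        idx = pd.Index(iids, name="iid")
        cols = pd.Index(phenotypes, name="phenotype")
        return cls(
            pd.DataFrame(lifetime, index=idx, columns=cols),
            pd.DataFrame(age, index=idx, columns=cols),
        )

    # -- queries -------------------------------------------------------------

    @property
    def phenotypes(self) -> list[str]:
        return list(self.status.columns)

    def _check(self, phenotype: str) -> None:
        if phenotype not in self.status.columns:
            raise PhenotypeError(f"unknown phenotype {phenotype!r}")

    def status_codes(self, phenotype: str) -> pd.Series:
        """Lifetime status codes (1/0/-1) indexed by iid."""
        self._check(phenotype)
        return self.status[phenotype]

    def lifetime_status(self, iid: str, phenotype: str) -> str:
        self._check(phenotype)
        return _STATUS[int(self.status.at[iid, phenotype])]

    def analysis_age(self, iid: str, phenotype: str) -> float:
        self._check(phenotype)
        return float(self.age.at[iid, phenotype])

    # -- transformations -----------------------------------------------------

    def add_composite(self, name: str, components: Sequence[str]) -> "PhenotypePanel":
        """Any-of composite column; analysis age = earliest component case age
        for cases, latest component data age for controls."""
        for c in components:
            self._check(c)
        import warnings as _warnings

        sub = self.status[list(components)].to_numpy()
        agesub = self.age[list(components)].to_numpy()
        lifetime = sub.max(axis=1).astype(np.int8)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-missing rows
            case_age = np.nanmin(np.where(sub == 1, agesub, np.nan), axis=1)
            ctrl_age = np.nanmax(np.where(sub >= 0, agesub, np.nan), axis=1)
        age = np.where(lifetime == 1, case_age, np.where(lifetime == 0, ctrl_age, np.nan))
        status = self.status.copy()
        ages = self.age.copy()
        status[name] = lifetime
        ages[name] = age
        return PhenotypePanel(status, ages)

    def apply_exclusions(self, exclusion_map: Mapping[str, Sequence[str]]) -> "PhenotypePanel":
        """Sensitivity-analysis exclusions: lifetime cases of any excluding
        phenotype are dropped (status -> missing) from the target phenotype's
        analyses; their data for other phenotypes is untouched."""
        for target, excluders in exclusion_map.items():
            self._check(target)
            for e in excluders:
                self._check(e)
        status = self.status.copy()
        ages = self.age.copy()
        for target, excluders in exclusion_map.items():
            if not excluders:
                continue
            excluded = (self.status[list(excluders)].to_numpy() == 1).any(axis=1)
            n_drop = int((excluded & (status[target].to_numpy() != -1)).sum())
            status.loc[excluded, target] = -1
            ages.loc[excluded, target] = np.nan
            logger.info("exclusions for %s: %d participants set to missing", target, n_drop)
        return PhenotypePanel(status, ages)

    # -- I/O -----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        long = self.status.stack(future_stack=True).rename("code").reset_index()
        long.columns = ["iid", "phenotype", "code"]
        long["lifetime_status"] = long["code"].map(_STATUS)
        long["analysis_age"] = self.age.stack(future_stack=True).to_numpy()
        long.drop(columns="code").to_csv(path, sep="\t", index=False)

    @staticmethod
    def read_assessments_tsv(path: str | Path) -> pd.DataFrame:
        """Read the long wave-level TSV (iid, phenotype, wave, status, age)."""
        return pd.read_csv(
            path, sep="\t", dtype={"iid": str, "phenotype": str, "wave": str}, na_values=["NA"]
        )


def summarize(panel: PhenotypePanel, ped=None) -> pd.DataFrame:
    """Study-population descriptives: N, per-phenotype case counts and
    prevalence among participants with data, sex split and mean (SD) age if a
    pedigree is given, and relative-count summaries."""
    rows: list[tuple[str, float]] = [("N", float(len(panel.status)))]
    if ped is not None:
        from . import pedigree as pedmod

        sex = ped.sex_series().reindex(panel.status.index)
        n_male = int((sex == pedmod.MALE).sum())
        rows.append(("male_n", float(n_male)))
        rows.append(("male_pct", 100.0 * n_male / len(sex)))
        for deg in (pedmod.FIRST, pedmod.SECOND):
            i_idx, _ = ped.degree_pair_indices(deg)
            counts = np.zeros(len(ped), dtype=np.int64)
            np.add.at(counts, i_idx, 1)
            counts = pd.Series(counts, index=ped.iids).reindex(panel.status.index, fill_value=0)
            has = counts > 0
            rows.append((f"{deg}_degree_relative_n", float(has.sum())))
            rows.append((f"{deg}_degree_relative_pct", 100.0 * has.mean()))
            if has.any():
                rows.append((f"median_{deg}_degree_relatives", float(counts[has].median())))
    ages = panel.age.to_numpy()
    if np.isfinite(ages).any():
        import warnings as _warnings

        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", RuntimeWarning)  # all-missing rows
            first_age = np.nanmin(ages, axis=1)
        rows.append(("mean_age", float(np.nanmean(first_age))))
        rows.append(("sd_age", float(np.nanstd(first_age, ddof=1))))
    for ph in panel.phenotypes:
        codes = panel.status[ph]
        n_case = int((codes == 1).sum())
        n_data = int((codes >= 0).sum())
        rows.append((f"{ph}_cases", float(n_case)))
        rows.append((f"{ph}_with_data", float(n_data)))
        if n_data:
            rows.append((f"{ph}_prevalence_pct", 100.0 * n_case / n_data))
    return pd.DataFrame(rows, columns=["statistic", "value"])
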