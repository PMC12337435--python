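"""Synthetic pedigrees and multi-wave binary phenotypes with known familial
correlations.

Families follow a three-generation template (founder couple, their children,
a married-in spouse and grandchildren, optionally a half-sib branch), so both
first- and second-degree relative pairs exist. Phenotypes arise from the
liability threshold model: per family the familial liability components G
have covariance A (x) C_familial — A the additive relationship matrix scaled
by the template's kinship structure, C_familial the cross-trait familial
covariance whose diagonal is the familial variance share of each trait and
whose off-diagonal entries are the cross-trait familial covariances, i.e. the
r_f values the pipeline should recover. Person-level residuals have
covariance R_within - C_familial (within-person cross-trait correlation minus
its familial part), so total liabilities are standardized and the marginal
prevalence of each trait is set by its threshold.

Lifetime cases are spread over assessment waves by a uniformly drawn onset
wave (a case appears from its onset wave onward), and each wave has its own
missingness probability, emulating staggered data collection and attrition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .pedigree import (
    FEMALE,
    MALE,
    IndividualRecord,
    Pedigree,
    build_pedigree,
    relationship_matrix,
)
from .phenotype import PhenotypePanel

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FamilyTemplate:
    """Generation structure of each simulated family.

    Default: founder couple, ``n_children`` children, the first child married
    to a founder spouse with ``n_grandchildren`` children; optionally the
    founder father has ``n_half_sibs`` children with a second partner
    (half-siblings of the main sibship).
    """

    n_children: int = 2
    n_grandchildren: int = 1
    n_half_sibs: int = 1

    def size(self) -> int:
        n = 2 + self.n_children + self.n_half_sibs
        if self.n_half_sibs:
            n += 1  # second partner
        if self.n_grandchildren:
            n += 1 + self.n_grandchildren  # spouse + grandchildren
        return n

    def records(self, fam: int, rng: np.random.Generator) -> tuple[list[IndividualRecord], list[int]]:
        """Pedigree records for family ``fam`` plus each member's generation."""
        if self.size() <= 2:
            raise ValueError("family template must contain children")
        p = f"F{fam}"
        recs = [
            IndividualRecord(f"{p}_gf", sex=MALE),
            IndividualRecord(f"{p}_gm", sex=FEMALE),
        ]
        gens = [0, 0]
        child_sexes = rng.random(self.n_children) < 0.5
        for c in range(self.n_children):
            recs.append(
                IndividualRecord(
                    f"{p}_c{c}",
                    father_iid=f"{p}_gf",
                    mother_iid=f"{p}_gm",
                    sex=MALE if child_sexes[c] else FEMALE,
                )
            )
            gens.append(1)
        if self.n_grandchildren:
            spouse_sex = FEMALE if child_sexes[0] else MALE
            recs.append(IndividualRecord(f"{p}_sp", sex=spouse_sex))
            gens.append(1)
            father = f"{p}_c0" if child_sexes[0] else f"{p}_sp"
            mother = f"{p}_sp" if child_sexes[0] else f"{p}_c0"
            for g in range(self.n_grandchildren):
                recs.append(
                    IndividualRecord(
                        f"{p}_g{g}",
                        father_iid=father,
                        mother_iid=mother,
                        sex=MALE if rng.random() < 0.5 else FEMALE,
                    )
                )
                gens.append(2)
        if self.n_half_sibs:
            recs.append(IndividualRecord(f"{p}_gm2", sex=FEMALE))
            gens.append(0)
            for h in range(self.n_half_sibs):
                recs.append(
                    IndividualRecord(
                        f"{p}_h{h}",
                        father_iid=f"{p}_gf",
                        mother_iid=f"{p}_gm2",
                        sex=MALE if rng.random() < 0.5 else FEMALE,
                    )
                )
                gens.append(1)
        return recs, gens


def familial_covariance(shares, rf_targets) -> np.ndarray:
    """Build C_familial from per-trait familial variance shares and a matrix
    (or scalar for two traits) of cross-trait r_f targets (the off-diagonal
    familial covariances on the standardized liability scale)."""
    shares = np.asarray(shares, dtype=float)
    T = len(shares)
    C = np.diag(shares)
    if np.isscalar(rf_targets):
        if T != 2:
            raise ValueError("scalar rf_target only valid for two traits")
        C[0, 1] = C[1, 0] = float(rf_targets)
    else:
        off = np.asarray(rf_targets, dtype=float)
        C = C + off - np.diag(np.diag(off))
    return C


@dataclass
class SimulationConfig:
    n_families: int
    phenotypes: list[str]
    prevalences: list[float]
    C_familial: np.ndarray
    R_within: np.ndarray | None = None  # default: identity
    covariate_effects: np.ndarray | None = None  # (T, 3): age, age^2, sex
    template: FamilyTemplate = field(default_factory=FamilyTemplate)
    waves: list[str] = field(default_factory=lambda: ["1A", "2A", "3A"])
    wave_offsets: list[float] = field(default_factory=lambda: [0.0, 4.0, 10.5])
    wave_missingness: list[float] = field(default_factory=lambda: [0.10, 0.20, 0.30])
    generation_age_means: list[float] = field(default_factory=lambda: [65.0, 40.0, 15.0])
    generation_age_sds: list[float] = field(default_factory=lambda: [8.0, 8.0, 5.0])
    emit_latent: bool = False
    seed: int = 0

    def __post_init__(self):
        T = len(self.phenotypes)
        self.prevalences = list(map(float, self.prevalences))
        if len(self.prevalences) != T:
            raise ValueError("one prevalence per phenotype required")
        if not all(0.0 < K < 1.0 for K in self.prevalences):
            raise ValueError("prevalences must lie in (0,1)")
        self.C_familial = np.asarray(self.C_familial, dtype=float)
        if self.C_familial.shape != (T, T):
            raise ValueError("C_familial dimension mismatch")
        if self.R_within is None:
            self.R_within = np.eye(T)
        self.R_within = np.asarray(self.R_within, dtype=float)
        for name, M in (("C_familial", self.C_familial), ("R_within", self.R_within)):
            if not np.allclose(M, M.T):
                raise ValueError(f"{name} must be symmetric")
            if np.linalg.eigvalsh(M).min() < -1e-10:
                raise ValueError(f"{name} must be positive semidefinite")
        shares = np.diag(self.C_familial)
        if ((shares < 0) | (shares >= 1)).any():
            raise ValueError("familial variance shares must lie in [0, 1)")
        resid = self.R_within - self.C_familial
        if np.linalg.eigvalsh(resid).min() < -1e-10:
            off = np.abs(resid - np.diag(np.diag(resid)))
            a, b = np.unravel_index(np.argmax(off), off.shape)
            raise ValueError(
                "residual covariance R_within - C_familial is not positive semidefinite "
                f"(offending pair: {self.phenotypes[a]}, {self.phenotypes[b]})"
            )
        if self.covariate_effects is None:
            self.covariate_effects = np.zeros((T, 3))
        self.covariate_effects = np.asarray(self.covariate_effects, dtype=float)
        if self.covariate_effects.shape != (T, 3):
            raise ValueError("covariate_effects must be (n_traits, 3): age, age^2, sex")
        if len(self.waves) != len(self.wave_offsets) or len(self.waves) != len(self.wave_missingness):
            raise ValueError("waves, wave_offsets and wave_missingness must align")


@dataclass
class WaveData:
    """Simulated wave-level assessments in cube form.

    ``status_cube``: (n_individuals, n_traits, n_waves) with 1/0/-1;
    ``age_cube``: matching ages (NaN where missing). ``latent`` optionally
    carries the underlying liabilities for test oracles.
    """

    iids: list[str]
    phenotypes: list[str]
    waves: list[str]
    status_cube: np.ndarray
    age_cube: np.ndarray
    latent: np.ndarray | None = None

    def to_panel(self) -> PhenotypePanel:
        return PhenotypePanel.from_cube(self.iids, self.phenotypes, self.status_cube, self.age_cube)

    def to_records(self) -> pd.DataFrame:
        n, T, W = self.status_cube.shape
        iid = np.repeat(self.iids, T * W)
        pheno = np.tile(np.repeat(self.phenotypes, W), n)
        wave = np.tile(self.waves, n * T)
        code = self.status_cube.reshape(-1).astype(float)
        status = np.where(code < 0, np.nan, code)
        return pd.DataFrame(
            {"iid": iid, "phenotype": pheno, "wave": wave, "status": status, "age": self.age_cube.reshape(-1)}
        )

    def write_tsv(self, path) -> None:
        df = self.to_records()
        df["status"] = df["status"].map({1.0: "1", 0.0: "0"}).fillna("NA")
        df["age"] = df["age"].round(2)
        df.to_csv(path, sep="\t", index=False, na_rep="NA")

    def write_latent_tsv(self, path) -> None:
        if self.latent is None:
            raise ValueError("latent liabilities were not emitted")
        pd.DataFrame(self.latent, index=pd.Index(self.iids, name="iid"), columns=self.phenotypes).to_csv(
            path, sep="\t"
        )


def simulate_pedigrees(cfg: SimulationConfig) -> Pedigree:
    """Seeded population of ``n_families`` independent template families."""
    if cfg.n_families < 1:
        raise ValueError("n_families must be >= 1")
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 0]))
    records: list[IndividualRecord] = []
    generations: list[int] = []
    for fam in range(cfg.n_families):
        recs, gens = cfg.template.records(fam, rng)
        records.extend(recs)
        generations.extend(gens)
    ped = build_pedigree(records)
    # generation labels in record order == pedigree order (no placeholders here)
    ped._generations = np.asarray(generations, dtype=np.int64)
    return ped


def _generations(ped: Pedigree) -> np.ndarray:
    gens = getattr(ped, "_generations", None)
    if gens is not None:
        return gens
    # fallback for externally built pedigrees: depth, with founders lifted to
    # one generation below their children's level when they married in
    gen = ped._depth.copy()
    for _ in range(3):
        for child in range(len(ped)):
            for par in (ped.father[child], ped.mother[child]):
                if par >= 0:
                    gen[par] = max(gen[par], gen[child] - 1)
    return gen


def _family_choleskys(ped: Pedigree) -> tuple[np.ndarray, list[list[int]]]:
    """Stacked Cholesky factors of the per-family relationship matrices,
    grouped (and cached) for batched liability draws."""
    cache = getattr(ped, "_sim_cache", None)
    if cache is not None:
        return cache
    relmats = relationship_matrix(ped)
    sizes = {len(members) for members, _ in relmats.values()}
    if len(sizes) != 1:
        # general case: keep per-family factors in a ragged list
        factors = [(members, np.linalg.cholesky(A)) for members, A in relmats.values()]
        ped._sim_cache = (None, factors)
        return ped._sim_cache
    members_list = [members for members, _ in relmats.values()]
    chol = np.stack([np.linalg.cholesky(A) for _, A in relmats.values()])
    ped._sim_cache = (chol, members_list)
    return ped._sim_cache


def _psd_factor(M: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(M)
    return vecs * np.sqrt(np.clip(vals, 0.0, None))


def simulate_phenotypes(ped: Pedigree, cfg: SimulationConfig) -> WaveData:
    """Draw liabilities, threshold them, and emit wave-level assessments."""
    rng = np.random.default_rng(np.random.SeedSequence([int(cfg.seed), 1]))
    n = len(ped)
    T = len(cfg.phenotypes)
    W = len(cfg.waves)

    gens = np.clip(_generations(ped), 0, len(cfg.generation_age_means) - 1)
    means = np.asarray(cfg.generation_age_means)[gens]
    sds = np.asarray(cfg.generation_age_sds)[gens]
    base_age = np.clip(rng.normal(means, sds), 3.0, 94.0)

    # familial components: per family G = cholA @ Z @ cholC', batched
    cholC = _psd_factor(cfg.C_familial)
    cholE = _psd_factor(cfg.R_within - cfg.C_familial)
    G = np.zeros((n, T))
    chol_stack, members = _family_choleskys(ped)
    if chol_stack is not None:
        m = chol_stack.shape[1]
        Z = rng.standard_normal((len(members), m, T))
        Gfam = np.einsum("fij,fjt->fit", chol_stack, Z) @ cholC.T
        idx = np.asarray(members).reshape(-1)
        G[idx] = Gfam.reshape(-1, T)
    else:
        for mem, Lf in members:
            Z = rng.standard_normal((len(mem), T))
            G[mem] = (Lf @ Z) @ cholC.T
    E = rng.standard_normal((n, T)) @ cholE.T
    L = G + E

    effects = cfg.covariate_effects
    has_effects = bool(np.any(effects != 0.0))
    if has_effects:
        sex01 = (ped.sex == FEMALE).astype(float)
        covs = np.column_stack([base_age, base_age**2, sex01])
        L = L + covs @ effects.T

    K = np.asarray(cfg.prevalences)
    if has_effects:
        # numeric calibration: empirical quantile of the realized liabilities
        thresholds = np.quantile(L, 1.0 - K, axis=0).diagonal()
    else:
        from scipy.stats import norm

        thresholds = norm.isf(K)
    lifetime_case = L > thresholds[None, :]
    realized = lifetime_case.mean(axis=0)
    tol = np.maximum(0.002, 3.0 / max(n, 1))
    if has_effects and np.any(np.abs(realized - K) > tol):
        worst = int(np.argmax(np.abs(realized - K)))
        raise RuntimeError(
            f"prevalence calibration failed for {cfg.phenotypes[worst]}: got {realized[worst]:.4f}, target {K[worst]:.4f}"
        )

    # wave-level records: cases appear from a uniform onset wave onward
    onset = rng.integers(0, W, size=(n, T))
    wave_idx = np.arange(W)[None, None, :]
    status = np.where(
        lifetime_case[:, :, None] & (wave_idx >= onset[:, :, None]), 1, 0
    ).astype(np.int8)
    miss = rng.random((n, T, W)) < np.asarray(cfg.wave_missingness)[None, None, :]
    status[miss] = -1

    age_cube = np.broadcast_to(
        (base_age[:, None] + np.asarray(cfg.wave_offsets)[None, :])[:, None, :], (n, T, W)
    ).copy()
    age_cube[status == -1] = np.nan

    return WaveData(
        iids=list(ped.iids),
        phenotypes=list(cfg.phenotypes),
        waves=list(cfg.waves),
        status_cube=status,
        age_cube=age_cube,
        latent=L if cfg.emit_latent else None,
    )
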