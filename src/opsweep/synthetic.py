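"""Synthetic cohort generator calibrated to the reference cohort.

The generator emulates the statistical structure the downstream analysis
assumes:

* the 3x3 skeletal-cell allocation with per-sex counts (exact reference
  allocation at n = 903, largest-remainder proportional or uniform
  otherwise);
* per-cell truncated-normal anatomy for the ten surrogate inputs plus the
  classification indicators SN-MP, FH-MP and ANB (SNB is derived exactly as
  SNA - ANB); ANB is truncated into its sagittal band and SN-MP / FH-MP into
  their vertical bands so the rule-based classifier reproduces the intended
  label for every record;
* outcomes linear in SN-OP:  y = b(x) + k(x) * SN_OP + couplings + noise,
  where the slope k and intercept b are smooth *surfaces over observable
  anatomy* rather than functions of the latent cell label.  Each surface is
  bilinear over a 3x3 knot grid in a two-dimensional discriminant score
  plane (a sagittal and a vertical score, linear in the nine non-SN-OP
  inputs), clamped outside the knot range.  Node values are solved so that
  the *cell-conditional mean* of k and of b equals the calibrated per-cell
  value exactly (Gauss-Hermite moment matching).  Making the coefficients
  functions of observed anatomy is what allows a regressor on the ten
  inputs to recover them; a latent-label intercept would be statistically
  unidentifiable from the inputs and would bias every recovered slope.

The partial derivative of the noise-free generating mean with respect to
SN-OP at any point equals the local slope surface value exactly: neither
the intercept surface nor the coupling terms involve SN-OP.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sps

from . import tables
from .classify import ClassificationRuleSet
from .data import CephRecord, Cohort, SkeletalClass
from .exceptions import ConfigurationError

__all__ = [
    "GeneratorConfig", "OutcomeSurfaces", "allocate_cells", "sample_record",
    "generate_cohort", "repeated_measures",
]

_SAMPLED_FIELDS = tables.INPUT_FEATURES + tables.CLASSIFIER_FEATURES
_NON_OP_INPUTS = tuple(f for f in tables.INPUT_FEATURES if f != "SN_OP")


def _default_stats() -> dict:
    return {f: dict(tables.FEATURE_STATS[f]) for f in _SAMPLED_FIELDS}


@dataclass
class GeneratorConfig:
    """Calibration and sampling options for the synthetic cohort.

    Defaults reproduce the reference-cohort conditions: n = 903 with the
    exact cell/sex allocation, per-cell anatomy moments, per-cell outcome
    coefficients, couplings alpha (S-Go and N-ANS into FHR, Go-Po into FA,
    all relative to the pooled cohort mean) and outcome noise SDs.
    """

    n: int = tables.TOTAL_N
    seed: int = 0
    allocation: str = "table3_exact"
    feature_stats: dict = field(default_factory=_default_stats)
    fhr_coefficients: dict = field(
        default_factory=lambda: dict(tables.FHR_COEFFICIENTS))
    fa_coefficients: dict = field(
        default_factory=lambda: dict(tables.FA_COEFFICIENTS))
    alpha_s_go: float = 0.10    # percent FHR per mm S-Go
    alpha_n_ans: float = -0.10  # percent FHR per mm N-ANS
    alpha_go_po: float = 0.05   # degrees FA per mm Go-Po
    sigma_fhr: float = 0.5      # percent
    sigma_fa: float = 0.8       # degrees
    truncation_sds: float = 4.0
    truncation_margin: float = 1e-3  # inset so CSV rounding cannot flip bands
    surface_form: str = "additive"   # 'additive' or 'bilinear'
    rules: ClassificationRuleSet = field(default_factory=ClassificationRuleSet)
    feature_corr: np.ndarray | None = None  # optional, over sampled fields

    def validate(self) -> None:
        if self.allocation not in ("table3_exact", "proportional", "uniform"):
            raise ConfigurationError(f"unknown allocation {self.allocation!r}")
        if self.allocation == "table3_exact" and self.n != tables.TOTAL_N:
            raise ConfigurationError(
                f"table3_exact allocation requires n = {tables.TOTAL_N}")
        if self.allocation != "table3_exact" and self.n < 9:
            raise ConfigurationError("n must be >= 9")
        for fname, stats in self.feature_stats.items():
            for cell in tables.CELLS:
                if cell not in stats:
                    raise ConfigurationError(
                        f"cell {cell} lacks calibration for {fname}")
                if stats[cell][1] < 0:
                    raise ConfigurationError(f"negative SD for {fname} {cell}")
        for coeffs in (self.fhr_coefficients, self.fa_coefficients):
            for cell in tables.CELLS:
                k, b = coeffs[cell]
                if not (np.isfinite(k) and np.isfinite(b)):
                    raise ConfigurationError("non-finite outcome coefficient")
        if self.sigma_fhr < 0 or self.sigma_fa < 0:
            raise ConfigurationError("outcome noise SDs must be >= 0")
        if self.surface_form not in ("additive", "bilinear", "hybrid"):
            raise ConfigurationError(
                f"unknown surface_form {self.surface_form!r}")
        if self.feature_corr is not None:
            m = np.asarray(self.feature_corr, float)
            if m.shape != (len(_SAMPLED_FIELDS),) * 2:
                raise ConfigurationError(
                    "feature_corr must be square over the sampled fields")

    # -- serialization ----------------------------------------------------
    def to_yaml(self, path: str | Path) -> None:
        d = {
            "n": self.n, "seed": self.seed, "allocation": self.allocation,
            "alpha_s_go": self.alpha_s_go, "alpha_n_ans": self.alpha_n_ans,
            "alpha_go_po": self.alpha_go_po,
            "sigma_fhr": self.sigma_fhr, "sigma_fa": self.sigma_fa,
            "truncation_sds": self.truncation_sds,
            "truncation_margin": self.truncation_margin,
            "surface_form": self.surface_form,
            "feature_stats": {
                fname: {"/".join(c): [float(v[0]), float(v[1])]
                        for c, v in stats.items()}
                for fname, stats in self.feature_stats.items()},
            "fhr_coefficients": {"/".join(c): [float(k), float(b)]
                                 for c, (k, b) in self.fhr_coefficients.items()},
            "fa_coefficients": {"/".join(c): [float(k), float(b)]
                                for c, (k, b) in self.fa_coefficients.items()},
        }
        if self.feature_corr is not None:
            d["feature_corr"] = np.asarray(self.feature_corr).tolist()
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        def cellkey(s):
            sag, _, vert = s.partition("/")
            return (sag, vert)
        kw = {k: d[k] for k in ("n", "seed", "allocation", "alpha_s_go",
                                "alpha_n_ans", "alpha_go_po", "sigma_fhr",
                                "sigma_fa", "truncation_sds",
                                "truncation_margin", "surface_form")
              if k in d}
        if "feature_stats" in d:
            kw["feature_stats"] = {
                fname: {cellkey(c): tuple(v) for c, v in stats.items()}
                for fname, stats in d["feature_stats"].items()}
        for key in ("fhr_coefficients", "fa_coefficients"):
            if key in d:
                kw[key] = {cellkey(c): tuple(v) for c, v in d[key].items()}
        if "feature_corr" in d:
            kw["feature_corr"] = np.asarray(d["feature_corr"], float)
        return cls(**kw)


# ---------------------------------------------------------------------------
# outcome coefficient surfaces


def _largest_remainder(quotas: np.ndarray, total: int) -> np.ndarray:
    floors = np.floor(quotas).astype(int)
    short = total - floors.sum()
    if short > 0:
        # stable: largest fractional part first, earlier index on ties
        order = np.argsort(-(quotas - floors), kind="stable")
        floors[order[:short]] += 1
    return floors


class OutcomeSurfaces:
    """Slope/intercept surfaces over the discriminant score plane.

    Deterministically derived from a :class:`GeneratorConfig`; no RNG.
    """

    _GH_ORDER = 25

    def __init__(self, config: GeneratorConfig):
        self.config = config
        st = config.feature_stats
        cells = list(tables.CELLS)
        self._weights = tables.cell_weights()

        self._pool_sd = np.array([
            max(np.mean([st[f][c][1] for c in cells]), 1e-12)
            for f in _NON_OP_INPUTS])
        mu = {c: np.array([st[f][c][0] for f in _NON_OP_INPUTS]) for c in cells}
        sd = {c: np.array([st[f][c][1] for f in _NON_OP_INPUTS]) for c in cells}
        std_mu = {c: mu[c] / self._pool_sd for c in cells}

        vert = np.mean([std_mu[(s, "hyper")] - std_mu[(s, "hypo")]
                        for s in tables.SAGITTAL], axis=0)
        sag = np.mean([std_mu[("III", v)] - std_mu[("II", v)]
                       for v in tables.VERTICAL], axis=0)
        for name, d in (("vertical", vert), ("sagittal", sag)):
            if np.linalg.norm(d) < 1e-9:
                raise ConfigurationError(
                    f"degenerate {name} discriminant direction")
        self._dirs = np.stack([sag / np.linalg.norm(sag),
                               vert / np.linalg.norm(vert)])  # 2 x 9

        raw_cent = {c: self._dirs @ std_mu[c] for c in cells}
        self._center = sum(w * raw_cent[c]
                           for w, c in zip(self._weights, cells))
        spread = np.array([
            np.std([raw_cent[c][0] for c in cells]),
            np.std([raw_cent[c][1] for c in cells])])
        self._scale = np.where(spread > 1e-12, spread, 1.0)
        cent = {c: (raw_cent[c] - self._center) / self._scale for c in cells}

        u_knots = np.array([np.mean([cent[(s, v)][0] for v in tables.VERTICAL])
                            for s in tables.SAGITTAL])
        v_knots = np.array([np.mean([cent[(s, v)][1] for s in tables.SAGITTAL])
                            for v in tables.VERTICAL])
        self._u_order = np.argsort(u_knots)
        self._v_order = np.argsort(v_knots)
        self._u_knots = u_knots[self._u_order]
        self._v_knots = v_knots[self._v_order]
        if (np.diff(self._u_knots).min() < 1e-9
                or np.diff(self._v_knots).min() < 1e-9):
            raise ConfigurationError("score knots are not distinct")

        covs = {}
        for c in cells:
            D = np.diag((sd[c] / self._pool_sd) ** 2)
            covs[c] = (self._dirs @ D @ self._dirs.T) / np.outer(
                self._scale, self._scale)

        # expected basis weights per cell under its score distribution
        x, w1 = np.polynomial.hermite_e.hermegauss(self._GH_ORDER)
        GX, GY = np.meshgrid(x, x)
        gw = np.outer(w1, w1).ravel()
        gw = gw / gw.sum()
        ncols = self._basis(np.zeros((1, 2))).shape[1]
        EW = np.empty((9, ncols))
        for i, c in enumerate(cells):
            evals, evecs = np.linalg.eigh(covs[c])
            L = evecs * np.sqrt(np.clip(evals, 0.0, None))
            pts = cent[c] + np.stack([GX.ravel(), GY.ravel()], 1) @ L.T
            EW[i] = gw @ self._basis(pts)
        bil_block = {"bilinear": EW, "hybrid": EW[:, 7:],
                     "additive": None}[config.surface_form]
        if bil_block is not None and np.linalg.cond(bil_block) > 1e8:
            raise ConfigurationError(
                "ill-conditioned moment system for outcome surfaces; "
                "cell score distributions are not separable enough")
        self._EW = EW

        pooled = self.pooled_feature_means()
        def couple_fhr(c):
            return (config.alpha_s_go * (st["S_Go"][c][0] - pooled["S_Go"])
                    + config.alpha_n_ans * (st["N_ANS"][c][0] - pooled["N_ANS"]))
        def couple_fa(c):
            return config.alpha_go_po * (st["Go_Po"][c][0] - pooled["Go_Po"])

        def solve(targets):
            t = np.asarray(targets, float)
            form = config.surface_form
            if form == "bilinear":
                return np.linalg.solve(EW, t)
            if form == "additive":
                # least-squares moment fit (minimum-norm)
                return np.linalg.lstsq(EW, t, rcond=None)[0]
            # hybrid: smooth additive fit, exact bilinear residual correction
            p = np.linalg.lstsq(EW[:, :7], t, rcond=None)[0]
            q = np.linalg.solve(EW[:, 7:], t - EW[:, :7] @ p)
            return np.concatenate([p, q])

        self._nodes = {
            ("FHR", "k"): solve([config.fhr_coefficients[c][0] for c in cells]),
            ("FHR", "b"): solve([config.fhr_coefficients[c][1] - couple_fhr(c)
                                 for c in cells]),
            ("FA", "k"): solve([config.fa_coefficients[c][0] for c in cells]),
            ("FA", "b"): solve([config.fa_coefficients[c][1] - couple_fa(c)
                                for c in cells]),
        }

    # -- geometry ---------------------------------------------------------
    def pooled_feature_means(self) -> dict[str, float]:
        st = self.config.feature_stats
        return {f: float(sum(w * st[f][c][0] for w, c in
                             zip(self._weights, tables.CELLS)))
                for f in _SAMPLED_FIELDS}

    def scores(self, F9: np.ndarray) -> np.ndarray:
        """Map n x 9 non-SN-OP anatomy to (sagittal, vertical) scores."""
        F9 = np.atleast_2d(np.asarray(F9, float))
        raw = (F9 / self._pool_sd) @ self._dirs.T
        return (raw - self._center) / self._scale

    @staticmethod
    def _interp1d_weights(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
        x = np.clip(x, knots[0], knots[-1])
        W = np.zeros((len(x), 3))
        for j in range(2):
            m = (x >= knots[j]) & (x <= knots[j + 1])
            t = (x[m] - knots[j]) / (knots[j + 1] - knots[j])
            W[m, j] = 1.0 - t
            W[m, j + 1] = t
        return W

    def _bilinear_weights(self, UV: np.ndarray) -> np.ndarray:
        Wu = self._interp1d_weights(UV[:, 0], self._u_knots)[:, self._u_order.argsort()]
        Wv = self._interp1d_weights(UV[:, 1], self._v_knots)[:, self._v_order.argsort()]
        # node order matches CELLS: sagittal-major, vertical minor
        return np.einsum("ni,nj->nij", Wu, Wv).reshape(len(UV), 9)

    def _additive_weights(self, UV: np.ndarray) -> np.ndarray:
        Wu = self._interp1d_weights(UV[:, 0], self._u_knots)[:, self._u_order.argsort()]
        Wv = self._interp1d_weights(UV[:, 1], self._v_knots)[:, self._v_order.argsort()]
        return np.concatenate([np.ones((len(UV), 1)), Wu, Wv], axis=1)

    def _basis(self, UV: np.ndarray) -> np.ndarray:
        """Surface basis at score points.

        'bilinear': full 3x3 tensor weights (9 columns, exact moment solve);
        'additive': [1 | u-hats | v-hats] (7 columns, least-squares moment
        fit; smoother and monotone between knots — the reference
        coefficient tables are additive in the two axes to ~0.01 in k);
        'hybrid': additive plus a bilinear correction solved exactly on the
        small additive residual (exact cell-conditional means, near-additive
        smoothness)."""
        form = self.config.surface_form
        if form == "bilinear":
            return self._bilinear_weights(UV)
        if form == "additive":
            return self._additive_weights(UV)
        return np.concatenate([self._additive_weights(UV),
                               self._bilinear_weights(UV)], axis=1)

    def coefficient(self, F9: np.ndarray, outcome: str, which: str) -> np.ndarray:
        """Evaluate the k or b surface at given non-SN-OP anatomy rows."""
        UV = self.scores(F9)
        return self._basis(UV) @ self._nodes[(outcome, which)]

    # -- generating mean --------------------------------------------------
    def mean_outcome(self, X10, outcome: str) -> np.ndarray:
        """Noise-free generating mean for n x 10 input rows (SN-OP last).

        d(mean)/d(SN_OP) equals the local slope surface value exactly.
        """
        X10 = np.atleast_2d(np.asarray(X10, float))
        names = list(tables.INPUT_FEATURES)
        F9 = X10[:, [names.index(f) for f in _NON_OP_INPUTS]]
        s = X10[:, names.index("SN_OP")]
        k = self.coefficient(F9, outcome, "k")
        b = self.coefficient(F9, outcome, "b")
        pooled = self.pooled_feature_means()
        cfg = self.config
        if outcome == "FHR":
            coup = (cfg.alpha_s_go * (X10[:, names.index("S_Go")] - pooled["S_Go"])
                    + cfg.alpha_n_ans * (X10[:, names.index("N_ANS")] - pooled["N_ANS"]))
        elif outcome == "FA":
            coup = cfg.alpha_go_po * (X10[:, names.index("Go_Po")] - pooled["Go_Po"])
        else:
            raise ValueError("outcome must be 'FHR' or 'FA'")
        return b + coup + k * s


# ---------------------------------------------------------------------------
# allocation and sampling


def allocate_cells(n: int, mode: str = "table3_exact",
                   seed: int | None = None) -> dict[tuple[str, str], tuple[int, int]]:
    """Per-cell (female, male) counts summing to n.

    ``table3_exact`` reproduces the reference allocation (requires n = 903);
    ``proportional`` scales the reference proportions by largest-remainder
    rounding (cell totals first, then the sex split within each cell);
    ``uniform`` spreads records evenly over the nine cells, with the pooled
    female share within each cell.  Deterministic; ``seed`` is accepted for
    interface symmetry but unused.
    """
    if mode == "table3_exact":
        if n != tables.TOTAL_N:
            raise ConfigurationError(
                f"table3_exact allocation requires n = {tables.TOTAL_N}, got {n}")
        return dict(tables.CELL_ALLOCATION)
    if n < 9:
        raise ConfigurationError("n must be >= 9")
    cells = list(tables.CELLS)
    if mode == "proportional":
        props = np.array([tables.cell_count(c) for c in cells], float)
        props /= props.sum()
    elif mode == "uniform":
        props = np.full(9, 1.0 / 9.0)
    else:
        raise ConfigurationError(f"unknown allocation mode {mode!r}")
    totals = _largest_remainder(props * n, n)
    out = {}
    for c, tot in zip(cells, totals):
        if mode == "proportional":
            f_share = tables.CELL_ALLOCATION[c][0] / tables.cell_count(c)
        else:
            f_share = tables.TOTAL_FEMALE / tables.TOTAL_N
        nf = int(_largest_remainder(np.array([f_share * tot,
                                              (1 - f_share) * tot]), int(tot))[0])
        out[c] = (nf, int(tot) - nf)
    return out


def _truncation_bounds(fname: str, cell: tuple[str, str],
                       config: GeneratorConfig) -> tuple[float, float]:
    mean, sd = config.feature_stats[fname][cell]
    lo = mean - config.truncation_sds * sd
    hi = mean + config.truncation_sds * sd
    eps = config.truncation_margin
    rules = config.rules
    if fname == "ANB":
        b_lo, b_hi = rules.anb_class_i
        band = {"I": (b_lo + eps, b_hi - eps),
                "II": (b_hi + eps, np.inf),
                "III": (-np.inf, b_lo - eps)}[cell[0]]
    elif fname == "SN_MP":
        b_lo, b_hi = rules.sn_mp_nor
        band = {"hypo": (-np.inf, b_lo - eps),
                "nor": (b_lo + eps, b_hi - eps),
                "hyper": (b_hi + eps, np.inf)}[cell[1]]
    elif fname == "FH_MP":
        b_lo, b_hi = rules.fh_mp_nor
        band = {"hypo": (-np.inf, b_lo - eps),
                "nor": (b_lo + eps, b_hi - eps),
                "hyper": (b_hi + eps, np.inf)}[cell[1]]
    else:
        band = (-np.inf, np.inf)
    lo, hi = max(lo, band[0]), min(hi, band[1])
    if not lo < hi:
        # truncation window collapsed: fall back to the criterion band centre
        raise ConfigurationError(
            f"empty truncation window for {fname} in cell {cell}")
    return lo, hi


def _sample_features(cell: tuple[str, str], n: int, config: GeneratorConfig,
                     rng: np.random.Generator) -> dict[str, np.ndarray]:
    """Truncated-normal anatomy draws for one cell (vectorized)."""
    vals: dict[str, np.ndarray] = {}
    if config.feature_corr is not None:
        corr = np.asarray(config.feature_corr, float)
        L = np.linalg.cholesky(corr)
        Z = rng.standard_normal((n, len(_SAMPLED_FIELDS))) @ L.T
        for j, fname in enumerate(_SAMPLED_FIELDS):
            mean, sd = config.feature_stats[fname][cell]
            lo, hi = _truncation_bounds(fname, cell, config)
            vals[fname] = np.clip(mean + sd * Z[:, j], lo, hi) if sd > 0 \
                else np.full(n, mean)
        return vals
    for fname in _SAMPLED_FIELDS:
        mean, sd = config.feature_stats[fname][cell]
        if sd == 0:
            vals[fname] = np.full(n, float(mean))
            continue
        lo, hi = _truncation_bounds(fname, cell, config)
        a, b = (lo - mean) / sd, (hi - mean) / sd
        vals[fname] = sps.truncnorm.rvs(a, b, loc=mean, scale=sd,
                                        size=n, random_state=rng)
    return vals


def _assemble_records(cell: tuple[str, str], n: int, sexes: list[str],
                      ids: list[str], config: GeneratorConfig,
                      surfaces: OutcomeSurfaces,
                      rng: np.random.Generator,
                      overrides: dict[str, float] | None = None
                      ) -> tuple[list[CephRecord], pd.DataFrame]:
    feats = _sample_features(cell, n, config, rng)
    if overrides:
        for fname, value in overrides.items():
            if fname not in feats:
                raise ConfigurationError(f"cannot override {fname!r}")
            feats[fname] = np.full(n, float(value))
    snb = feats["SNA"] - feats["ANB"]  # exact identity on synthesis

    F9 = np.column_stack([feats[f] for f in _NON_OP_INPUTS])
    s = feats["SN_OP"]
    pooled = surfaces.pooled_feature_means()
    k_fhr = surfaces.coefficient(F9, "FHR", "k")
    b_fhr = (surfaces.coefficient(F9, "FHR", "b")
             + config.alpha_s_go * (feats["S_Go"] - pooled["S_Go"])
             + config.alpha_n_ans * (feats["N_ANS"] - pooled["N_ANS"]))
    k_fa = surfaces.coefficient(F9, "FA", "k")
    b_fa = (surfaces.coefficient(F9, "FA", "b")
            + config.alpha_go_po * (feats["Go_Po"] - pooled["Go_Po"]))
    fhr = b_fhr + k_fhr * s + rng.normal(0.0, config.sigma_fhr, n) \
        if config.sigma_fhr > 0 else b_fhr + k_fhr * s
    fa = b_fa + k_fa * s + rng.normal(0.0, config.sigma_fa, n) \
        if config.sigma_fa > 0 else b_fa + k_fa * s

    records = []
    for i in range(n):
        records.append(CephRecord(
            id=ids[i], sex=sexes[i],
            N_ANS=feats["N_ANS"][i], S_N=feats["S_N"][i],
            Ptm_A=feats["Ptm_A"][i], SNA=feats["SNA"][i],
            NA_FH=feats["NA_FH"][i], PP_FH=feats["PP_FH"][i],
            Go_Po=feats["Go_Po"][i], Go_Co=feats["Go_Co"][i],
            S_Go=feats["S_Go"][i], SN_OP=s[i],
            FHR=fhr[i], FA=fa[i], SNB=snb[i], ANB=feats["ANB"][i],
            FH_MP=feats["FH_MP"][i], SN_MP=feats["SN_MP"][i]))
    truth = pd.DataFrame({
        "id": ids, "sagittal": cell[0], "vertical": cell[1],
        "k_FHR": k_fhr, "b_FHR": b_fhr, "k_FA": k_fa, "b_FA": b_fa})
    return records, truth


def sample_record(cell: tuple[str, str], config: GeneratorConfig,
                  rng: np.random.Generator,
                  overrides: dict[str, float] | None = None) -> CephRecord:
    """Draw one record from a cell; ``overrides`` force feature values
    (e.g. a fixed SN_OP) before outcomes are computed."""
    config.validate()
    if cell not in tables.CELLS:
        raise ConfigurationError(f"unknown cell {cell!r}")
    surfaces = OutcomeSurfaces(config)
    recs, _ = _assemble_records(cell, 1, ["F"], ["R0001"], config, surfaces,
                                rng, overrides)
    return recs[0]


def generate_cohort(config: GeneratorConfig | None = None
                    ) -> tuple[Cohort, pd.DataFrame]:
    """Generate (cohort, truth table); a pure function of the config.

    The truth table has one row per record: intended skeletal cell and the
    record-level generating coefficients k/b for both outcomes (b is the
    record's effective intercept, couplings included, so the noise-free
    generating mean is exactly b + k * SN_OP).
    """
    config = GeneratorConfig() if config is None else config
    config.validate()
    surfaces = OutcomeSurfaces(config)
    alloc = allocate_cells(config.n, config.allocation, config.seed)
    rng = np.random.default_rng(config.seed)

    records: list[CephRecord] = []
    labels: list[SkeletalClass] = []
    truths: list[pd.DataFrame] = []
    counter = 0
    for cell in tables.CELLS:
        nf, nm = alloc[cell]
        n = nf + nm
        if n == 0:
            continue
        ids = [f"P{counter + i + 1:04d}" for i in range(n)]
        counter += n
        sexes = ["F"] * nf + ["M"] * nm
        recs, truth = _assemble_records(cell, n, sexes, ids, config,
                                        surfaces, rng)
        records.extend(recs)
        labels.extend([SkeletalClass(*cell)] * n)
        truths.append(truth)
    cohort = Cohort(records, labels=labels, provenance="generated",
                    seed=config.seed)
    return cohort, pd.concat(truths, ignore_index=True)


# ---------------------------------------------------------------------------
# repeated measurements (reliability experiment emulation)


def repeated_measures(cohort: Cohort, n_raters: int = 3, n_sessions: int = 2,
                      noise_sd: dict[str, float] | None = None,
                      noise_fraction: float = 0.25,
                      rater_bias_sd: float = 0.0,
                      seed: int | None = None
                      ) -> tuple[np.ndarray, tuple[str, ...]]:
    """Simulate the rater-reliability experiment.

    Returns ``(ratings, fields)`` with ratings shaped
    (rater, session, record, field): true value plus independent normal
    noise, plus an optional constant per-rater/per-field bias.  ``noise_sd``
    gives absolute per-field SDs; otherwise each field's SD is
    ``noise_fraction`` times its empirical SD in the cohort (the default
    0.25 corresponds to a consistency ICC of about 1/(1+0.25^2) = 0.94,
    inside the 0.88-0.98 reliability range this emulation targets).
    """
    if n_raters < 1 or n_sessions < 1:
        raise ConfigurationError("need at least one rater and one session")
    fields = tables.ALL_FIELDS
    df = cohort.to_frame()
    truth = df[list(fields)].to_numpy(float)  # records x fields
    if noise_sd is not None:
        sds = np.array([float(noise_sd.get(f, 0.0)) for f in fields])
    else:
        if noise_fraction < 0:
            raise ConfigurationError("noise_fraction must be >= 0")
        sds = noise_fraction * truth.std(axis=0, ddof=1)
    if np.any(sds < 0):
        raise ConfigurationError("noise SDs must be >= 0")
    rng = np.random.default_rng(seed)
    shape = (n_raters, n_sessions) + truth.shape
    ratings = truth[None, None] + rng.standard_normal(shape) * sds
    if rater_bias_sd > 0:
        bias = rng.normal(0.0, rater_bias_sd,
                          (n_raters, 1, 1, len(fields))) * \
            np.where(sds > 0, 1.0, 0.0)
        ratings = ratings + bias
    return ratings, fields
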