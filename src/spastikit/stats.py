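"""The study's statistical battery.

Paired t-tests compare components between the paretic and non-paretic side;
a two-way repeated-measures ANOVA (side x angle, both within-subject) tests
the stiffness profiles, with a one-way repeated ANOVA plus all-pairs
Bonferroni post hoc within each side; Pearson correlations relate the
modulus and clinical motor score to the components; Spearman correlations
handle the ordinal spasticity grade. Two-sided tests throughout, alpha 0.05.

The repeated-measures partitioning is computed from scratch (each
within-subject effect is tested against its own subject-by-factor error
stratum); sphericity is not corrected by default, with a Greenhouse-Geisser
flag available for the angle terms.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import DataError

ALPHA_DEFAULT = 0.05

#: Ordinal coding of the modified Ashworth scale, with "1+" between 1 and 2.
MAS_ORDINAL = {"0": 0, "1": 1, "1+": 2, "2": 3, "3": 4, "4": 5}


@dataclass
class TestResult:
    """One hypothesis test: statistic, degrees of freedom, p, estimate, n."""

    statistic: float
    df: object
    p: float
    estimate: float
    n: int
    method: str = ""
    note: str = ""

    def to_dict(self) -> dict:
        d = {"statistic": self.statistic, "df": self.df, "p": self.p,
             "estimate": self.estimate, "n": self.n, "method": self.method}
        if self.note:
            d["note"] = self.note
        return d


def _as_pair(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DataError("x and y must be 1-D arrays of equal length")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise DataError("inputs must be finite")
    return x, y


def paired_t(x, y) -> TestResult:
    """Classical two-sided paired t-test on the within-subject differences.

    Degenerate cases: identical pairs give t = 0, p = 1; zero-variance
    differences with a nonzero mean give the limiting p = 0 (flagged).
    """
    x, y = _as_pair(x, y)
    n = x.size
    if n < 2:
        raise DataError("paired t-test needs n >= 2")
    d = x - y
    sd = d.std(ddof=1)
    mean = d.mean()
    if sd == 0.0:
        if mean == 0.0:
            return TestResult(0.0, n - 1, 1.0, 0.0, n, "paired t", "identical pairs")
        t = np.inf if mean > 0 else -np.inf
        return TestResult(float(t), n - 1, 0.0, float(mean), n, "paired t",
                          "zero-variance differences; limiting p")
    res = sps.ttest_rel(x, y)
    return TestResult(float(res.statistic), n - 1, float(res.pvalue),
                      float(mean), n, "paired t")


def pearson(x, y) -> TestResult:
    """Pearson correlation with the two-sided p from the t transform
    (n - 2 degrees of freedom)."""
    x, y = _as_pair(x, y)
    n = x.size
    if n < 3:
        raise DataError("Pearson correlation needs n >= 3")
    if x.std() == 0.0 or y.std() == 0.0:
        raise DataError("undefined correlation: zero variance")
    r, p = sps.pearsonr(x, y)
    return TestResult(float(r), n - 2, float(p), float(r), n, "Pearson r")


def _exact_spearman_p(rx: np.ndarray, ry: np.ndarray, rho_obs: float) -> float:
    """Two-sided exact permutation p for Spearman's rho (feasible n <= 8)."""
    n = rx.size
    perms = np.array(list(permutations(range(n))))
    ry_perm = ry[perms]  # (n!, n)
    rxc = rx - rx.mean()
    ryc = ry_perm - ry_perm.mean(axis=1, keepdims=True)
    denom = np.sqrt((rxc ** 2).sum() * (ryc ** 2).sum(axis=1))
    rho = (ryc @ rxc) / denom
    return float(np.mean(np.abs(rho) >= abs(rho_obs) - 1e-12))


def spearman(x, y) -> TestResult:
    """Spearman rank correlation (average ranks for ties).

    The p-value uses an exact permutation null for n <= 8 and the t
    approximation with n - 2 degrees of freedom otherwise.
    """
    x, y = _as_pair(x, y)
    n = x.size
    if n < 3:
        raise DataError("Spearman correlation needs n >= 3")
    rx = sps.rankdata(x)
    ry = sps.rankdata(y)
    if rx.std() == 0.0 or ry.std() == 0.0:
        raise DataError("undefined correlation: all values tied")
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= 8:
        p = _exact_spearman_p(rx, ry, rho)
        method = "Spearman rho (exact permutation)"
    else:
        if abs(rho) >= 1.0:
            p = 0.0
        else:
            t = rho * np.sqrt((n - 2) / (1.0 - rho ** 2))
            p = float(2.0 * sps.t.sf(abs(t), n - 2))
        method = "Spearman rho (t approximation)"
    return TestResult(rho, n - 2, p, rho, n, method)


def mas_to_ordinal(grade: str) -> int:
    """Map a modified Ashworth grade string to its ordinal code."""
    key = str(grade).strip()
    if key not in MAS_ORDINAL:
        raise DataError(f"unknown MAS grade {grade!r}; expected one of "
                        f"{sorted(MAS_ORDINAL)}")
    return MAS_ORDINAL[key]


# ---------------------------------------------------------------------------
# repeated-measures ANOVA


def _pivot_cube(tab: pd.DataFrame, dv: str, subject: str,
                factors: tuple[str, ...]) -> tuple[np.ndarray, list]:
    """Arrange a long table into a (subjects x levels...) array, demanding a
    complete crossing with exactly one observation per cell."""
    for col in (dv, subject) + factors:
        if col not in tab.columns:
            raise DataError(f"table missing column {col!r}")
    counts = tab.groupby([subject, *factors], sort=True)[dv].count()
    subjects = sorted(tab[subject].unique())
    levels = [sorted(tab[f].unique()) for f in factors]
    full = pd.MultiIndex.from_product([subjects, *levels],
                                      names=[subject, *factors])
    missing = full.difference(counts.index)
    if len(missing):
        raise DataError(f"incomplete crossing; missing cells: {list(missing[:10])}")
    if (counts > 1).any():
        dup = counts[counts > 1].index[:10]
        raise DataError(f"duplicated cells (one observation required): {list(dup)}")
    wide = tab.set_index([subject, *factors])[dv].reindex(full)
    shape = (len(subjects), *(len(lv) for lv in levels))
    return wide.to_numpy(dtype=float).reshape(shape), levels


def _contrast_basis(k: int) -> np.ndarray:
    """Orthonormal basis of the (k-1)-dimensional contrast space."""
    centering = np.eye(k) - np.ones((k, k)) / k
    u, s, _ = np.linalg.svd(centering)
    return u[:, : k - 1].T


def _gg_epsilon(scores: np.ndarray, contrast: np.ndarray) -> float:
    """Greenhouse-Geisser epsilon from the covariance of contrast scores."""
    sigma = np.cov(scores, rowvar=False)
    m = contrast @ sigma @ contrast.T
    k1 = contrast.shape[0]
    tr = np.trace(m)
    denom = k1 * np.trace(m @ m)
    if denom <= 0:
        return 1.0
    return float(min(1.0, tr ** 2 / denom))


def _effect_f(ss_eff: float, df_eff: int, ss_err: float, df_err: int) -> tuple[float, float]:
    if ss_eff <= 1e-12:
        return 0.0, 1.0
    if ss_err <= 1e-12:
        return float("inf"), 0.0
    f = (ss_eff / df_eff) / (ss_err / df_err)
    return float(f), float(sps.f.sf(f, df_eff, df_err))


def rm_anova_2way(tab: pd.DataFrame, dv: str = "value",
                  subject: str = "subject_id",
                  factors: tuple[str, str] = ("side", "angle_deg"),
                  gg: bool = False) -> pd.DataFrame:
    """Two-way fully within-subject ANOVA.

    Each effect (factor A, factor B, A x B) is tested against its own
    subject-by-effect interaction stratum. Requires one observation per
    (subject, A, B) cell. With ``gg=True`` a Greenhouse-Geisser corrected
    p-value is added per effect.

    Returns a data frame with one row per effect: SS, df, F, p (and eps,
    p_gg when requested).
    """
    X, levels = _pivot_cube(tab, dv, subject, tuple(factors))
    s, a, b = X.shape
    if s < 2:
        raise DataError("repeated-measures ANOVA needs >= 2 subjects")
    grand = X.mean()
    m_s = X.mean(axis=(1, 2))
    m_a = X.mean(axis=(0, 2))
    m_b = X.mean(axis=(0, 1))
    m_ab = X.mean(axis=0)
    m_sa = X.mean(axis=2)
    m_sb = X.mean(axis=1)

    ss_a = s * b * np.sum((m_a - grand) ** 2)
    ss_b = s * a * np.sum((m_b - grand) ** 2)
    ss_ab = s * np.sum((m_ab - m_a[:, None] - m_b[None, :] + grand) ** 2)
    ss_as = b * np.sum((m_sa - m_s[:, None] - m_a[None, :] + grand) ** 2)
    ss_bs = a * np.sum((m_sb - m_s[:, None] - m_b[None, :] + grand) ** 2)
    ss_total = np.sum((X - grand) ** 2)
    ss_subj = a * b * np.sum((m_s - grand) ** 2)
    ss_abs = ss_total - ss_subj - ss_a - ss_b - ss_ab - ss_as - ss_bs

    rows = []
    specs = [
        (factors[0], ss_a, a - 1, ss_as, (a - 1) * (s - 1)),
        (factors[1], ss_b, b - 1, ss_bs, (b - 1) * (s - 1)),
        (f"{factors[0]} * {factors[1]}", ss_ab, (a - 1) * (b - 1),
         ss_abs, (a - 1) * (b - 1) * (s - 1)),
    ]
    for name, ss_eff, df_eff, ss_err, df_err in specs:
        f, p = _effect_f(ss_eff, df_eff, ss_err, df_err)
        rows.append({"effect": name, "SS": float(ss_eff), "df1": df_eff,
                     "SS_error": float(ss_err), "df2": df_err, "F": f, "p": p})
    out = pd.DataFrame(rows)
    if gg:
        ca, cb = _contrast_basis(a), _contrast_basis(b)
        eps = [
            _gg_epsilon(X.mean(axis=2), ca),
            _gg_epsilon(X.mean(axis=1), cb),
            _gg_epsilon(X.reshape(s, a * b), np.kron(ca, cb)),
        ]
        p_gg = []
        for e, row in zip(eps, rows):
            if np.isfinite(row["F"]) and row["F"] > 0:
                p_gg.append(float(sps.f.sf(row["F"], e * row["df1"], e * row["df2"])))
            else:
                p_gg.append(row["p"])
        out["eps"] = eps
        out["p_gg"] = p_gg
    return out


def oneway_rm_anova_with_bonferroni(tab: pd.DataFrame, dv: str = "value",
                                    subject: str = "subject_id",
                                    factor: str = "angle_deg") -> dict:
    """One-way within-subject ANOVA plus all-pairs Bonferroni post hoc.

    The omnibus F tests the factor against the subject-by-factor stratum.
    Every pair of levels is then compared with a paired t-test, and each raw
    p is multiplied by the number of pairs (capped at 1).
    """
    X, levels = _pivot_cube(tab, dv, subject, (factor,))
    lv = levels[0]
    s, k = X.shape
    if s < 2:
        raise DataError("repeated-measures ANOVA needs >= 2 subjects")
    grand = X.mean()
    m_s = X.mean(axis=1)
    m_k = X.mean(axis=0)
    ss_k = s * np.sum((m_k - grand) ** 2)
    ss_err = np.sum((X - m_s[:, None] - m_k[None, :] + grand) ** 2)
    f, p = _effect_f(ss_k, k - 1, ss_err, (k - 1) * (s - 1))
    omnibus = TestResult(f, (k - 1, (k - 1) * (s - 1)), p,
                         float(np.ptp(m_k)), s, "one-way RM ANOVA")
    n_pairs = k * (k - 1) // 2
    pairs = []
    for i, j in combinations(range(k), 2):
        res = paired_t(X[:, i], X[:, j])
        pairs.append({
            "level_a": lv[i], "level_b": lv[j],
            "mean_diff": float(X[:, i].mean() - X[:, j].mean()),
            "t": res.statistic, "p_raw": res.p,
            "p_bonferroni": min(1.0, n_pairs * res.p),
        })
    return {"omnibus": omnibus, "pairwise": pd.DataFrame(pairs)}


# ---------------------------------------------------------------------------
# study battery


def _mu_at(profiles: pd.DataFrame, side: str, angle: float) -> pd.Series:
    sel = profiles[(profiles["side"] == side) & (profiles["angle_deg"] == angle)]
    return sel.set_index("subject_id")["mean_mu"]


def _mu_mean(profiles: pd.DataFrame, side: str) -> pd.Series:
    sel = profiles[profiles["side"] == side]
    return sel.groupby("subject_id")["mean_mu"].mean()


def _safe(testfunc, x, y) -> dict:
    try:
        return testfunc(np.asarray(x, float), np.asarray(y, float)).to_dict()
    except DataError as exc:
        return {"error": str(exc)}


def study_battery(components: pd.DataFrame, profiles: pd.DataFrame,
                  clinical: pd.DataFrame, alpha: float = ALPHA_DEFAULT,
                  gg: bool = False) -> dict:
    """Run the full statistical battery of the study design.

    ``components``: subject_id, side, nc_N, ec_N, vc_N.
    ``profiles``: subject_id, side, angle_deg, mean_mu.
    ``clinical``: subject_id, fma, mas.

    Correlations with the modulus are computed both against the modulus at
    30 deg extension and against the across-angle mean modulus, labelled
    separately.
    """
    report: dict = {"alpha": alpha}

    comp = components.pivot_table(index="subject_id", columns="side",
                                  values=["nc_N", "ec_N", "vc_N"])
    side_tests = {}
    for label, col in (("NC", "nc_N"), ("EC", "ec_N"), ("VC", "vc_N")):
        pair = comp[col].dropna()
        side_tests[label] = _safe(paired_t, pair["paretic"], pair["non_paretic"])
    report["component_side_contrast"] = side_tests

    long = profiles.rename(columns={"mean_mu": "value"})[
        ["subject_id", "side", "angle_deg", "value"]]
    try:
        report["modulus_rm_anova"] = rm_anova_2way(long, gg=gg).to_dict(orient="records")
    except DataError as exc:
        report["modulus_rm_anova"] = {"error": str(exc)}
    angle_effects = {}
    for side in ("paretic", "non_paretic"):
        try:
            res = oneway_rm_anova_with_bonferroni(long[long["side"] == side])
            angle_effects[side] = {
                "omnibus": res["omnibus"].to_dict(),
                "pairwise": res["pairwise"].to_dict(orient="records"),
            }
        except DataError as exc:
            angle_effects[side] = {"error": str(exc)}
    report["modulus_angle_effect"] = angle_effects

    per_angle = {}
    for angle in sorted(profiles["angle_deg"].unique()):
        mu_p = _mu_at(profiles, "paretic", angle)
        mu_n = _mu_at(profiles, "non_paretic", angle)
        common = mu_p.index.intersection(mu_n.index)
        per_angle[str(int(angle))] = _safe(paired_t, mu_p.loc[common], mu_n.loc[common])
    report["modulus_side_contrast_per_angle"] = per_angle

    comp_p = components[components["side"] == "paretic"].set_index("subject_id")
    clin = clinical.set_index("subject_id")
    mu30 = _mu_at(profiles, "paretic", 30)
    mu_mean = _mu_mean(profiles, "paretic")

    def aligned(a: pd.Series, b: pd.Series):
        common = a.dropna().index.intersection(b.dropna().index)
        return a.loc[common], b.loc[common]

    pearson_block = {}
    for label, series in (("EC", comp_p["ec_N"]), ("VC", comp_p["vc_N"]),
                          ("NC", comp_p["nc_N"])):
        x, y = aligned(mu30, series)
        pearson_block[f"mu_at_30_vs_{label}"] = _safe(pearson, x, y)
        x, y = aligned(mu_mean, series)
        pearson_block[f"mu_mean_vs_{label}"] = _safe(pearson, x, y)
        x, y = aligned(clin["fma"].astype(float), series)
        pearson_block[f"FMA_vs_{label}"] = _safe(pearson, x, y)
    x, y = aligned(clin["fma"].astype(float), mu_mean)
    pearson_block["FMA_vs_mu_mean"] = _safe(pearson, x, y)
    report["pearson"] = pearson_block

    mas_ord = clin["mas"].map(mas_to_ordinal).astype(float)
    spearman_block = {}
    for label, series in (("NC", comp_p["nc_N"]), ("EC", comp_p["ec_N"]),
                          ("VC", comp_p["vc_N"]), ("mu_at_30", mu30),
                          ("mu_mean", mu_mean)):
        x, y = aligned(mas_ord, series)
        spearman_block[f"MAS_vs_{label}"] = _safe(spearman, x, y)
    report["spearman"] = spearman_block
    return report
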