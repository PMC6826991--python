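"""Drug–gene interaction scoring from dose series of CPPs.

For each mutant dose series Y_i (one CPP at doses D_i, D_0 = 0) and the
reference-culture summaries R_i, interaction is quantified as:

    K_i = Y_i - R_i                  per-dose departure from the reference
    K_0 = Y_0 - R_0                  the "shift": the mutant's drug-free
                                     phenotype, subtracted from the whole series
    L_i = K_i - K_0                  drug-specific departure
    L_i = A + B * D_i                ordinary least squares over all doses
    INT = A + B * D_max              the interaction value at the top dose
    z   = (INT - mean(REF_INT)) / SD(REF_INT)

Reference cultures, scored identically, provide the null distribution;
knockdown (DAmP) strains are standardized against their own stratum because
their CPP distribution differs from the reference. Special-value rules:
cultures with no growth curve get Y_i = 0 for K and r, while for L (whose
no-growth asymptote is infinite) the value Y_i_max is substituted — the
largest Y_i among cultures whose carrying capacity is within 2 SD of the
reference mean at that dose — and observed outliers above Y_i_max are capped
at it. A culture that fails to grow even without drug cannot be scored; it is
flagged and downstream profile assembly assigns the sentinel 0.0001.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import CPPS
from .growth import array_id

logger = logging.getLogger(__name__)

ENHANCER, SUPPRESSOR, NONE, CONFLICT = "enhancer", "suppressor", "none", "conflict"

INTERACTION_COLUMNS = [
    "strain", "strain_class", "culture", "drug", "cpp",
    "shift", "A", "B", "INT", "z", "class", "flagged", "no_growth_at_d0",
]


@dataclass
class ReferenceStats:
    """Per-dose reference summaries plus stratum INT statistics for a drug."""

    drug: str
    doses: np.ndarray
    r_mean: pd.DataFrame   # index dose, columns CPPs: mean over growing refs
    r_sd: pd.DataFrame     # same shape: sample SD over growing refs
    y_max: pd.DataFrame    # same shape: Y_i_max (NaN where no qualifying culture)
    degenerate_sd: bool    # any reference SD exactly 0 (identical cultures)
    int_stats: dict[tuple[str, str], tuple[float, float]] = field(default_factory=dict)
    # (stratum, cpp) -> (mean INT, SD INT); strata: "reference", "knockdown"
    _cache: dict = field(default_factory=dict, repr=False, compare=False)

    def r_mean_array(self, cpp: str) -> np.ndarray:
        key = ("r_mean", cpp)
        if key not in self._cache:
            self._cache[key] = self.r_mean[cpp].to_numpy(dtype=float)
        return self._cache[key]

    def y_max_array(self, cpp: str) -> np.ndarray:
        key = ("y_max", cpp)
        if key not in self._cache:
            self._cache[key] = self.y_max[cpp].to_numpy(dtype=float)
        return self._cache[key]


@dataclass
class DoseProfile:
    """One culture's dose series for one drug: Y arrays per CPP, aligned to doses."""

    strain: str
    strain_class: str  # reference | knockout | knockdown
    culture: str
    drug: str
    doses: np.ndarray
    y: dict[str, np.ndarray]       # cpp -> Y_i
    no_growth: np.ndarray          # bool per dose

    @property
    def no_growth_at_d0(self) -> bool:
        return bool(self.no_growth[0])


def compute_reference_stats(
    cpp_table: pd.DataFrame, drug: str, ref_strain: str = "REF"
) -> ReferenceStats:
    """Per-dose reference means/SDs and Y_i_max for one drug.

    R_i and its SD are taken over growing reference cultures; Y_i_max per
    CPP is the maximum over *all* growing cultures whose K lies within 2 SD
    below the reference K mean at that dose. Raises if any dose has fewer
    than 2 growing reference cultures.
    """
    sub = cpp_table[cpp_table["drug"] == drug]
    if sub.empty:
        raise ValueError(f"no cultures for drug {drug!r}")
    doses = np.sort(sub["dose"].unique())
    refs = sub[(sub["strain"] == ref_strain) & (~sub["no_growth"])]

    counts = refs.groupby("dose").size().reindex(doses, fill_value=0)
    bad = [f"{d:g}" for d, c in counts.items() if c < 2]
    if bad:
        raise ValueError(
            f"{drug}: fewer than 2 growing reference cultures at dose(s) {', '.join(bad)}"
        )
    r_mean = refs.groupby("dose")[list(CPPS)].mean().reindex(doses)
    r_sd = refs.groupby("dose")[list(CPPS)].std(ddof=1).reindex(doses)

    growing = sub[~sub["no_growth"]]
    k_floor = (r_mean["K"] - 2.0 * r_sd["K"]).reindex(doses)
    rows = []
    for d in doses:
        at = growing[growing["dose"] == d]
        ok = at[at["K"] >= k_floor.loc[d]]
        rows.append(
            {cpp: (ok[cpp].max() if len(ok) else np.nan) for cpp in CPPS} | {"dose": d}
        )
    y_max = pd.DataFrame(rows).set_index("dose")

    degenerate = bool((r_sd.to_numpy() == 0).any())
    return ReferenceStats(drug, doses, r_mean, r_sd, y_max, degenerate)


def build_profiles(
    cpp_table: pd.DataFrame,
    drug: str,
    ref_strain: str = "REF",
    kd_strains: frozenset[str] | set[str] = frozenset(),
) -> list[DoseProfile]:
    """Assemble per-culture dose profiles for one drug.

    A culture is identified by (strain, array, row, col), where the array id
    is the plate id with its dose token stripped — the same physical array
    position printed across the dose series. Profiles missing any dose are
    dropped (logged via a count in the caller if needed).
    """
    sub = cpp_table[cpp_table["drug"] == drug].copy()
    sub["array"] = sub["plate"].map(array_id)
    doses = np.sort(sub["dose"].unique())
    sub = sub.sort_values(
        ["strain", "array", "row", "col", "dose"], kind="stable"
    ).reset_index(drop=True)
    dose_arr = sub["dose"].to_numpy(dtype=float)
    y_arr = {cpp: sub[cpp].to_numpy(dtype=float) for cpp in CPPS}
    ng_arr = sub["no_growth"].to_numpy(dtype=bool)

    profiles = []
    for (strain, arr, row, col), idx in sub.groupby(
        ["strain", "array", "row", "col"], sort=True
    ).indices.items():
        if not np.array_equal(dose_arr[idx], doses):
            continue
        if strain == ref_strain:
            cls = "reference"
        elif strain in kd_strains:
            cls = "knockdown"
        else:
            cls = "knockout"
        profiles.append(
            DoseProfile(
                strain=strain,
                strain_class=cls,
                culture=f"{arr}:{row}:{col}",
                drug=drug,
                doses=doses.astype(float),
                y={cpp: y_arr[cpp][idx] for cpp in CPPS},
                no_growth=ng_arr[idx],
            )
        )
    return profiles


def substitute_ymax(profile: DoseProfile, stats: ReferenceStats) -> DoseProfile:
    """Apply the special-value rules to one profile (returns a new profile).

    K and r: no-growth doses get Y_i = 0. L: a culture that grew at D_0 but
    not at D_i gets Y_i_max(L, D_i); any observed L above Y_i_max is capped
    at it. A profile with no growth at D_0 is returned unchanged — it is
    unscorable and flagged downstream.
    """
    if profile.no_growth_at_d0:
        return profile
    y = {cpp: profile.y[cpp].copy() for cpp in CPPS}
    ng = profile.no_growth
    for cpp in ("K", "r"):
        y[cpp][ng] = 0.0
    ymax_l = stats.y_max_array("L")
    for i in range(len(profile.doses)):
        needs = ng[i] or (np.isfinite(y["L"][i]) and y["L"][i] > ymax_l[i])
        if not needs:
            continue
        if not np.isfinite(ymax_l[i]):
            raise ValueError(
                f"Y_i_max undefined for L at dose {profile.doses[i]:g} "
                f"({stats.drug}) but substitution required for {profile.strain}"
            )
        y["L"][i] = ymax_l[i]
    out = DoseProfile(
        profile.strain, profile.strain_class, profile.culture, profile.drug,
        profile.doses, y, ng,
    )
    return out


def score_interaction(profile: DoseProfile, stats: ReferenceStats) -> pd.DataFrame:
    """Shift, regression and INT for one (already substituted) profile.

    Returns one row per CPP with columns shift, A, B, INT, flagged. An
    unscorable profile (no growth at D_0, or < 3 usable dose points) carries
    NaN statistics and flagged=True.
    """
    return pd.DataFrame(_score_rows(profile, stats))


def _score_rows(profile: DoseProfile, stats: ReferenceStats) -> list[dict]:
    """score_interaction worker: one dict per CPP (avoids a DataFrame per
    profile on the hot path)."""
    d = profile.doses
    d_max = float(d.max())
    rows = []
    for cpp in CPPS:
        rec = {
            "strain": profile.strain,
            "strain_class": profile.strain_class,
            "culture": profile.culture,
            "drug": profile.drug,
            "cpp": cpp,
            "shift": np.nan, "A": np.nan, "B": np.nan, "INT": np.nan,
            "flagged": True,
            "no_growth_at_d0": profile.no_growth_at_d0,
        }
        if not profile.no_growth_at_d0:
            y = profile.y[cpp]
            r_i = stats.r_mean_array(cpp)
            k_i = y - r_i
            k_0 = k_i[0]
            l_i = k_i - k_0
            usable = np.isfinite(l_i)
            if usable.sum() >= 3:
                A, B = _ols_line(d[usable], l_i[usable])
                rec.update(
                    shift=float(k_0), A=A, B=B,
                    INT=A + B * d_max, flagged=False,
                )
        rows.append(rec)
    return rows


def _ols_line(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Least-squares intercept A and slope B of y = A + B x (normal equations)."""
    xm, ym = x.mean(), y.mean()
    dx = x - xm
    B = float(np.dot(dx, y - ym) / np.dot(dx, dx))
    A = float(ym - B * xm)
    return A, B


def standardize(results: pd.DataFrame, atol: float = 1e-12) -> pd.DataFrame:
    """Attach interaction z-scores, standardizing each stratum per the design.

    Knockout strains (and references themselves) are standardized against the
    reference-culture INT distribution; knockdown strains against the
    knockdown stratum. Sample SD (ddof=1). A stratum SD of exactly 0 (only
    possible in a noiseless world) yields z = 0 for INTs equal to the stratum
    mean and NaN for the rest, with a logged warning.
    """
    out = results.copy()
    out["z"] = np.nan
    for (drug, cpp), grp in results.groupby(["drug", "cpp"], sort=False):
        ok = grp[~grp["flagged"]]
        for stratum, member_classes in (
            ("reference", ("reference", "knockout")),
            ("knockdown", ("knockdown",)),
        ):
            base = ok[ok["strain_class"] == stratum] if stratum == "knockdown" else ok[
                ok["strain_class"] == "reference"
            ]
            targets = out.index[
                out["drug"].eq(drug) & out["cpp"].eq(cpp)
                & out["strain_class"].isin(member_classes) & ~out["flagged"]
            ]
            if len(targets) == 0:
                continue
            if len(base) < 2:
                raise ValueError(
                    f"{drug}/{cpp}: stratum {stratum!r} has < 2 scored cultures"
                )
            ints = base["INT"].to_numpy(dtype=float)
            mean, sd = float(ints.mean()), float(ints.std(ddof=1))
            if sd == 0.0:
                # degenerate stratum (e.g. a noiseless simulation): INTs equal
                # to the stratum mean are exactly null (z = 0); any other INT
                # cannot be standardized against zero variance and stays NaN
                logger.warning(
                    "%s/%s: zero SD in stratum %r; emitting z=0 for null INTs only",
                    drug, cpp, stratum,
                )
                vals = out.loc[targets, "INT"].to_numpy(dtype=float)
                zvals = np.where(np.abs(vals - mean) <= atol, 0.0, np.nan)
                out.loc[targets, "z"] = zvals
                continue
            out.loc[targets, "z"] = (out.loc[targets, "INT"] - mean) / sd
    return out


def classify(z_L: float, z_K: float, threshold: float = 2.0) -> str:
    """Interaction class from the L and K z-scores (inclusive thresholds).

    Enhancer: z_L >= threshold or z_K <= -threshold (the deletion makes the
    drug more toxic). Suppressor: z_L <= -threshold or z_K >= threshold.
    Both rule sets firing at once is flagged "conflict"; missing scores only
    ever weaken a call.
    """
    enh = sup = False
    if np.isfinite(z_L):
        enh |= z_L >= threshold
        sup |= z_L <= -threshold
    if np.isfinite(z_K):
        enh |= z_K <= -threshold
        sup |= z_K >= threshold
    if enh and sup:
        return CONFLICT
    if enh:
        return ENHANCER
    if sup:
        return SUPPRESSOR
    return NONE


def attach_classes(results: pd.DataFrame, threshold: float = 2.0) -> pd.DataFrame:
    """Per-(culture, drug) class from that drug's z_L and z_K, set on all CPP rows.

    Vectorized mirror of :func:`classify` (NaN comparisons are False, so a
    missing score never fires a rule, matching the scalar path)."""
    out = results.copy()
    z = out.pivot_table(
        index=["strain", "culture", "drug"], columns="cpp", values="z", dropna=False
    )
    z_l = z["L"].to_numpy(dtype=float) if "L" in z else np.full(len(z), np.nan)
    z_k = z["K"].to_numpy(dtype=float) if "K" in z else np.full(len(z), np.nan)
    with np.errstate(invalid="ignore"):
        enh = (z_l >= threshold) | (z_k <= -threshold)
        sup = (z_l <= -threshold) | (z_k >= threshold)
    labels = np.select(
        [enh & sup, enh, sup], [CONFLICT, ENHANCER, SUPPRESSOR], default=NONE
    )
    cls = pd.DataFrame({"class": labels}, index=z.index).reset_index()
    out = out.drop(columns=["class"], errors="ignore").merge(
        cls, on=["strain", "culture", "drug"], how="left"
    )
    out["class"] = out["class"].fillna(NONE)
    out.loc[out["flagged"], "class"] = NONE
    return out


def score_all(
    cpp_table: pd.DataFrame,
    drug: str,
    ref_strain: str = "REF",
    kd_strains: frozenset[str] | set[str] = frozenset(),
    threshold: float = 2.0,
) -> pd.DataFrame:
    """Full step-by-step scoring of one drug: reference stats, substitution,
    per-culture regression, stratified z-scores, classification.

    Returns the tidy interaction table (one row per culture × CPP)."""
    stats = compute_reference_stats(cpp_table, drug, ref_strain=ref_strain)
    profiles = build_profiles(cpp_table, drug, ref_strain=ref_strain, kd_strains=kd_strains)
    rows: list[dict] = []
    for p in profiles:
        rows.extend(_score_rows(substitute_ymax(p, stats), stats))
    results = pd.DataFrame(rows)
    results = standardize(results)
    results = attach_classes(results, threshold=threshold)
    # record stratum stats for reuse / reporting
    for (drug_, cpp), grp in results.groupby(["drug", "cpp"], sort=False):
        refs = grp[(grp["strain_class"] == "reference") & ~grp["flagged"]]
        if len(refs) >= 2:
            stats.int_stats[("reference", cpp)] = (
                float(refs["INT"].mean()), float(refs["INT"].std(ddof=1))
            )
        kds = grp[(grp["strain_class"] == "knockdown") & ~grp["flagged"]]
        if len(kds) >= 2:
            stats.int_stats[("knockdown", cpp)] = (
                float(kds["INT"].mean()), float(kds["INT"].std(ddof=1))
            )
    results.attrs["reference_stats"] = stats
    return results[INTERACTION_COLUMNS + []]
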