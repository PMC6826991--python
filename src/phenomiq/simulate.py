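"""Synthetic phenomic experiment generator.

Emulates quantitative high-throughput cell array phenotyping (Q-HTCP): 384-culture
agar arrays imaged kinetically, one array position per culture, the same array
printed once per (drug, dose) condition so that a position's dose series is a
biological replicate series. Mutant strains carry planted drug–gene interaction
structure (a dose-0 "shift" of their proliferation parameters plus a
linear-in-dose displacement under drug), which the scoring pipeline should
recover; ground truth is returned alongside for recovery tests.

Also generates the ancillary inputs the downstream stages consume: flat
gene→GO-term annotations, yeast→human homology maps with homology-class
labels, and cell-line expression/drug-sensitivity matrices with planted
underexpression-sensitivity (UES) / overexpression-sensitivity (OES) genes.

All generators are pure functions of (config, seed): a fixed seed reproduces
byte-identical tables.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .config import CPPS, SimulationConfig, StrainEffects

TIMESERIES_COLUMNS = ["plate", "row", "col", "strain", "drug", "dose", "time_h", "intensity"]

ARRAY_ROWS, ARRAY_COLS = 16, 24  # 384-culture array geometry
ARRAY_SIZE = ARRAY_ROWS * ARRAY_COLS


def logistic_curve(t: np.ndarray, K: float, r: float, l: float) -> np.ndarray:
    """G(t) = K / (1 + exp(-r (t - l))): K carrying capacity, r max specific
    growth rate (1/h), l time at half carrying capacity (h)."""
    return K * expit(r * (np.asarray(t, dtype=float) - l))


def mutant_strain_names(config: SimulationConfig) -> list[str]:
    """Deterministic mutant roster: YKO_0001.. plus any planted-effect strains
    with names outside that series (appended, sorted)."""
    auto = [f"YKO_{i + 1:04d}" for i in range(config.n_mutant_strains)]
    extra = sorted(set(config.planted_effects) - set(auto))
    return auto + extra


def reference_cpps(config: SimulationConfig, drug: str, dose: float) -> dict[str, float]:
    """Reference-strain CPPs at a dose: untreated parameters displaced
    linearly in dose by the drug's stated dose response."""
    K, r, l = config.reference_params
    resp = config.reference_dose_response.get(drug, {})
    return {
        "K": K + resp.get("K", 0.0) * dose,
        "r": r + resp.get("r", 0.0) * dose,
        "L": l + resp.get("L", 0.0) * dose,
    }


def mutant_cpps(
    config: SimulationConfig, effects: StrainEffects, drug: str, dose: float
) -> dict[str, float]:
    base = reference_cpps(config, drug, dose)
    return {
        cpp: base[cpp] + effects.shift_of(cpp) + effects.slope_of(drug, cpp) * dose
        for cpp in CPPS
    }


def _positions(n: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Array index, row, col for culture indices 0..n-1 on stacked 384 arrays."""
    idx = np.arange(n)
    return idx // ARRAY_SIZE, (idx % ARRAY_SIZE) // ARRAY_COLS, idx % ARRAY_COLS


def generate_plate_experiment(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate the full plate experiment.

    Returns
    -------
    timeseries : DataFrame
        Long format, one row per (culture, timepoint):
        ``plate,row,col,strain,drug,dose,time_h,intensity``. Plate ids are
        ``{drug}_a{array:02d}_d{dose_index}``; a culture keeps its
        (array, row, col) across the dose series.
    ground_truth : DataFrame
        One row per mutant strain: planted shifts, per-drug true INT
        (slope × D_max) per CPP, and the true interaction class per drug
        (enhancer / suppressor / none, from the signs of the planted L/K
        slopes).
    """
    config.require_valid()
    rng = np.random.default_rng(config.seed)
    times = np.asarray(config.timepoints, dtype=float)
    nt = times.size

    mutants = mutant_strain_names(config)
    n_ref = config.n_reference_cultures
    # culture roster: references first (replicate positions), then mutants
    strains = [config.ref_strain] * n_ref + mutants
    effects = [StrainEffects()] * n_ref + [
        config.planted_effects.get(s, StrainEffects()) for s in mutants
    ]
    n_cult = len(strains)
    arrays, rows, cols = _positions(n_cult)

    frames = []
    for drug in config.doses_by_drug:
        doses = [float(d) for d in config.doses_by_drug[drug]]
        for di, dose in enumerate(doses):
            params = np.empty((n_cult, 3))
            ref_p = reference_cpps(config, drug, dose)
            params[:n_ref] = (ref_p["K"], ref_p["r"], ref_p["L"])
            for j, eff in enumerate(effects[n_ref:], start=n_ref):
                p = mutant_cpps(config, eff, drug, dose)
                params[j] = (p["K"], p["r"], p["L"])

            curves = params[:, 0:1] * expit(
                params[:, 1:2] * (times[None, :] - params[:, 2:3])
            )
            no_growth = rng.random(n_cult) < config.no_growth_fraction
            curves[no_growth] = config.baseline
            if config.noise_sd > 0:
                curves = curves + rng.normal(0.0, config.noise_sd, curves.shape)
            np.clip(curves, 0.0, None, out=curves)

            frames.append(
                pd.DataFrame(
                    {
                        "plate": np.repeat(
                            np.array([f"{drug}_a{a:02d}_d{di}" for a in arrays]), nt
                        ),
                        "row": np.repeat(rows, nt),
                        "col": np.repeat(cols, nt),
                        "strain": np.repeat(np.array(strains, dtype=object), nt),
                        "drug": drug,
                        "dose": dose,
                        "time_h": np.tile(times, n_cult),
                        "intensity": curves.ravel(),
                    }
                )
            )

    timeseries = pd.concat(frames, ignore_index=True)
    ground_truth = _ground_truth(config, mutants)
    return timeseries, ground_truth


def _ground_truth(config: SimulationConfig, mutants: Sequence[str]) -> pd.DataFrame:
    rows = []
    for strain in mutants:
        eff = config.planted_effects.get(strain, StrainEffects())
        rec: dict = {"strain": strain}
        for cpp in CPPS:
            rec[f"shift_{cpp}"] = eff.shift_of(cpp)
        for drug, doses in config.doses_by_drug.items():
            d_max = float(max(doses))
            for cpp in CPPS:
                rec[f"int_{drug}_{cpp}"] = eff.slope_of(drug, cpp) * d_max
            slope_l = eff.slope_of(drug, "L")
            slope_k = eff.slope_of(drug, "K")
            if slope_l > 0 or slope_k < 0:
                cls = "enhancer"
            elif slope_l < 0 or slope_k > 0:
                cls = "suppressor"
            else:
                cls = "none"
            rec[f"class_{drug}"] = cls
        rows.append(rec)
    return pd.DataFrame(rows)


def generate_go_annotations(
    n_genes: int,
    n_terms: int,
    term_size_range: tuple[int, int],
    seed: int,
    gene_names: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Flat two-column gene→term annotation table with unique gene sets per term."""
    lo, hi = term_size_range
    if lo > hi:
        raise ValueError(f"term_size_range inverted: {term_size_range}")
    if hi > n_genes:
        raise ValueError("term sizes cannot exceed n_genes")
    genes = (
        list(gene_names)
        if gene_names is not None
        else [f"YKO_{i + 1:04d}" for i in range(n_genes)]
    )
    if len(genes) != n_genes:
        raise ValueError("gene_names length must equal n_genes")
    rng = np.random.default_rng(seed)
    seen: set[frozenset] = set()
    records = []
    for t in range(n_terms):
        for _ in range(100):
            size = int(rng.integers(lo, hi + 1))
            members = frozenset(rng.choice(n_genes, size=size, replace=False))
            if members not in seen:
                seen.add(members)
                break
        else:  # pragma: no cover - would need a pathological size/term ratio
            raise RuntimeError("could not draw a unique gene set for a term")
        term = f"GO:{t + 1:07d}"
        records.extend((genes[g], term) for g in sorted(members))
    return pd.DataFrame(records, columns=["gene", "term"])


def generate_homology_map(
    yeast_genes: Sequence[str],
    n_human_genes: int,
    class_mix: tuple[float, float, float],
    seed: int,
) -> pd.DataFrame:
    """Yeast→human homolog table with class labels.

    class_mix gives proportions of (one-to-one, one-to-many, many-to-many)
    yeast genes. Human partners are drawn from a fresh pool so the label is
    consistent with the realized mapping cardinality by construction;
    many-to-many genes are grouped in pairs/triples sharing their partners
    (a leftover singleton group degrades to one-to-many, label adjusted).
    """
    yeast_genes = list(yeast_genes)
    if not yeast_genes:
        raise ValueError("yeast gene list is empty")
    if abs(sum(class_mix) - 1.0) > 1e-9:
        raise ValueError("class_mix proportions must sum to 1")
    rng = np.random.default_rng(seed)
    classes = rng.choice(3, size=len(yeast_genes), p=list(class_mix))

    pool = iter(f"HS_{i + 1:05d}" for i in range(n_human_genes))

    def take(k: int) -> list[str]:
        out = []
        for _ in range(k):
            try:
                out.append(next(pool))
            except StopIteration:
                raise ValueError("n_human_genes too small for requested map") from None
        return out

    rows: list[tuple[str, str, str]] = []
    mm_group: list[str] = []

    def flush_mm_group() -> None:
        if not mm_group:
            return
        if len(mm_group) == 1:  # cannot be many-to-many alone
            for h in take(int(rng.integers(2, 5))):
                rows.append((mm_group[0], h, "one-to-many"))
        else:
            humans = take(int(rng.integers(2, 4)))
            for y in mm_group:
                for h in humans:
                    rows.append((y, h, "many-to-many"))
        mm_group.clear()

    for gene, cls in zip(yeast_genes, classes):
        if cls == 0:
            rows.append((gene, take(1)[0], "one-to-one"))
        elif cls == 1:
            for h in take(int(rng.integers(2, 5))):
                rows.append((gene, h, "one-to-many"))
        else:
            mm_group.append(gene)
            if len(mm_group) == int(rng.integers(2, 4)):
                flush_mm_group()
    flush_mm_group()
    return pd.DataFrame(rows, columns=["yeast_gene", "human_gene", "homology_class"])


def generate_pharmaco_dataset(
    n_cell_lines: int,
    human_genes: Sequence[str],
    tissues: Sequence[str],
    planted: Mapping[str, tuple[str, float]],
    seed: int,
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Cell-line expression matrix plus drug sensitivity with planted structure.

    planted maps gene -> (direction, effect_size) with direction in
    {"UES", "OES", "null"}. Sensitivity is a continuous AAC-like value in
    [0, 1]; a UES gene's expression is *negatively* related to sensitivity
    (underexpression sensitizes), an OES gene's positively, null genes are
    independent. Expression is genes × cell lines, unit-variance noise.
    """
    if n_cell_lines < 10:
        raise ValueError("n_cell_lines must be >= 10")
    for gene, (direction, _) in planted.items():
        if direction not in ("UES", "OES", "null"):
            raise ValueError(f"unknown direction {direction!r} for gene {gene}")
    rng = np.random.default_rng(seed)
    lines = [f"CL_{i + 1:04d}" for i in range(n_cell_lines)]
    tissue = pd.Series(
        rng.choice(list(tissues), size=n_cell_lines), index=lines, name="tissue"
    )
    sens = pd.Series(rng.beta(2.0, 5.0, size=n_cell_lines), index=lines, name="sensitivity")
    z_sens = (sens - sens.mean()) / sens.std(ddof=1)

    expr = rng.normal(0.0, 1.0, size=(len(human_genes), n_cell_lines))
    sign = {"UES": -1.0, "OES": 1.0, "null": 0.0}
    for i, gene in enumerate(human_genes):
        direction, beta = planted.get(gene, ("null", 0.0))
        s = sign[direction] * beta
        if s != 0.0:
            expr[i] += s * z_sens.to_numpy()
    expr_df = pd.DataFrame(expr, index=list(human_genes), columns=lines)
    expr_df.index.name = "gene"
    return expr_df, sens, tissue
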