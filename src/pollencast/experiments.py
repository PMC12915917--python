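"""Benchmark and characterization experiments.

The benchmark compares the model roster across forecast horizons and taxa
on a year-grouped split: 70% of calendar years train, the rest test, so no
year contributes to both sides.  Each (taxon, horizon) pair uses one split
shared by every model.  Regression is scored by MAE/RMSE, classification by
overall accuracy, on held-out years only.

The characterization stage reports tree-model feature importances,
normalized mutual information of every input variable with the pollen
class, and weather-to-pollen-class association rules.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import magn as magn_mod
from .features import WindowSpec, build_sequence_dataset, build_tabular_dataset
from .io_ingest import extract_seasons
from .metrics import accuracy, mae, rmse, scheme_for
from .models import (
    ALL_FAMILIES,
    SEQUENCE_FAMILIES,
    ModelSpec,
    fit_predict,
    split_xy,
)
from .synthetic import default_model, simulate_dataset

__all__ = [
    "ExperimentConfig",
    "year_grouped_split",
    "run_experiment1",
    "run_experiment2",
    "render_report",
]

logger = logging.getLogger(__name__)

TREE_FAMILIES = ("decision_tree", "random_forest", "boosted_trees")


@dataclass(frozen=True)
class ExperimentConfig:
    """Settings shared by the benchmark and characterization runs."""

    taxa: tuple[str, ...] = ("Betula", "Poaceae")
    horizons: tuple[int, ...] = (1, 4, 7)
    window: int = 14
    split_fraction: float = 0.7
    seed: int = 0
    roster: tuple[str, ...] = ALL_FAMILIES
    years: int = 12  # synthetic years when no files are given
    min_support: float = 0.05
    min_confidence: float = 0.5
    model_hyperparams: dict = field(default_factory=dict)

    def __post_init__(self):
        if not 0.0 < self.split_fraction < 1.0:
            raise ValueError("split_fraction must lie in (0, 1)")
        if not self.horizons:
            raise ValueError("horizons must be non-empty")
        unknown = set(self.roster) - set(ALL_FAMILIES)
        if unknown:
            raise ValueError(f"unknown model families: {sorted(unknown)}")


def year_grouped_split(years, fraction: float = 0.7, seed: int = 0):
    """Random disjoint partition of calendar years into train/test sets.

    ``|train| = round-half-up(fraction * |years|)``, at least one year on
    each side.  Deterministic in the seed.
    """
    years = sorted(set(int(y) for y in years))
    if len(years) < 2:
        raise ValueError("need at least 2 distinct years to split")
    if not 0.0 < fraction < 1.0:
        raise ValueError("fraction must lie in (0, 1)")
    n_train = int(np.floor(fraction * len(years) + 0.5))  # round half-up
    n_train = min(max(n_train, 1), len(years) - 1)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(years))
    train = sorted(years[i] for i in perm[:n_train])
    test = sorted(years[i] for i in perm[n_train:])
    return train, test


def _load_or_simulate(config: ExperimentConfig, taxon: str):
    """Synthetic dataset for a taxon (file-based sources go through
    io_ingest and the same downstream path)."""
    model = default_model(taxon)
    return simulate_dataset(model, years=config.years, seed=config.seed)


def _benchmark_one(
    config: ExperimentConfig,
    taxon: str,
    horizon: int,
    seasons,
    meteo,
) -> tuple[list[dict], dict]:
    """All roster models on one (taxon, horizon) cell, shared split."""
    scheme = scheme_for(taxon)
    spec = WindowSpec(w=config.window, n=horizon)
    table = build_tabular_dataset(seasons, meteo, spec, scheme)
    seq = build_sequence_dataset(seasons, meteo, spec, scheme)

    years = sorted(table["year"].unique())
    train_years, test_years = year_grouped_split(
        years, config.split_fraction, seed=config.seed + horizon
    )
    tab_tr = table[table["year"].isin(train_years)].reset_index(drop=True)
    tab_te = table[table["year"].isin(test_years)].reset_index(drop=True)
    seq_mask_tr = np.isin(seq.year, train_years)
    seq_mask_te = np.isin(seq.year, test_years)

    from .features import SequenceDataset

    def subset(mask):
        return SequenceDataset(
            pollen=seq.pollen[mask],
            meteo=seq.meteo[mask],
            target=seq.target[mask],
            target_class=seq.target_class[mask],
            date=seq.date[mask],
            year=seq.year[mask],
            spec=seq.spec,
        )

    seq_tr, seq_te = subset(seq_mask_tr), subset(seq_mask_te)

    rows = []
    manifest = {
        "taxon": taxon,
        "horizon": horizon,
        "train_years": train_years,
        "test_years": test_years,
        "n_train": len(tab_tr),
        "n_test": len(tab_te),
    }
    y_true = tab_te["target"].to_numpy(dtype=float)
    cls_true = tab_te["target_class"].to_numpy(dtype=object)
    seq_true = seq_te.target
    seq_cls_true = seq_te.target_class

    for family in config.roster:
        hp = config.model_hyperparams.get(family, {})
        is_seq = family in SEQUENCE_FAMILIES
        train, test = (seq_tr, seq_te) if is_seq else (tab_tr, tab_te)
        yt = seq_true if is_seq else y_true
        ct = seq_cls_true if is_seq else cls_true
        try:
            reg_spec = ModelSpec(family, "regression", hyperparams=hp, seed=config.seed)
            fit_r, out_r = fit_predict(reg_spec, train, test, scheme=scheme)
            cls_spec = ModelSpec(family, "classification", hyperparams=hp, seed=config.seed)
            fit_c, out_c = fit_predict(cls_spec, train, test, scheme=scheme)
            rows.append(
                {
                    "taxon": taxon,
                    "horizon": horizon,
                    "model": family,
                    "accuracy": accuracy(ct, out_c["prediction"]),
                    "accuracy_from_regression": accuracy(ct, out_r["class_prediction"]),
                    "mae": mae(yt, out_r["prediction"]),
                    "rmse": rmse(yt, out_r["prediction"]),
                    "fit_seconds": fit_r.fit_seconds + fit_c.fit_seconds,
                    "peak_memory_mb": (fit_r.peak_memory_bytes + fit_c.peak_memory_bytes) / 2**20,
                    "error": "",
                }
            )
        except Exception as e:  # record and continue with the other models
            logger.exception("model %s failed on %s h=%d", family, taxon, horizon)
            rows.append(
                {
                    "taxon": taxon,
                    "horizon": horizon,
                    "model": family,
                    "accuracy": np.nan,
                    "accuracy_from_regression": np.nan,
                    "mae": np.nan,
                    "rmse": np.nan,
                    "fit_seconds": np.nan,
                    "peak_memory_mb": np.nan,
                    "error": repr(e),
                }
            )
    return rows, manifest


def run_experiment1(config: ExperimentConfig, data: dict | None = None):
    """Benchmark every roster model across taxa and horizons.

    ``data`` optionally maps taxon -> (seasons, meteo); otherwise the
    calibrated synthetic generator provides the series.  Returns the
    results table (sorted by accuracy, ties by ascending MAE, within each
    taxon/horizon cell) and a per-cell split manifest.
    """
    all_rows, manifests = [], []
    for taxon in config.taxa:
        if data and taxon in data:
            seasons, meteo = data[taxon]
        else:
            ds = _load_or_simulate(config, taxon)
            seasons, meteo = extract_seasons(ds.pollen), ds.meteo
        for horizon in config.horizons:
            rows, manifest = _benchmark_one(config, taxon, horizon, seasons, meteo)
            all_rows.extend(rows)
            manifests.append(manifest)
    results = pd.DataFrame(all_rows)
    results = (
        results.sort_values(
            ["taxon", "horizon", "accuracy", "mae"],
            ascending=[True, True, False, True],
            kind="stable",
        ).reset_index(drop=True)
    )
    return results, manifests


#: base-feature view used for the mutual-information ranking: the last
#: usable pollen observation plus the ten meteorological forecast values.
def _mi_feature_view(table: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in table.columns if c.endswith("__lag0") or c.startswith("pollen__lag")]
    return table[cols].rename(columns=lambda c: c.split("__")[0] + ("_past" if c.startswith("pollen") else ""))


def run_experiment2(config: ExperimentConfig, data: dict | None = None) -> dict:
    """Characterize the seasons: importances, normalized MI, rules.

    Returns, per taxon, the feature-importance shares of the best tree
    model from the benchmark, normalized-MI shares of the base input
    variables against the pollen class, and the mined weather-to-class
    association rules.  Shares are percentages summing to 100.
    """
    report: dict[str, dict] = {}
    for taxon in config.taxa:
        if data and taxon in data:
            seasons, meteo = data[taxon]
        else:
            ds = _load_or_simulate(config, taxon)
            seasons, meteo = extract_seasons(ds.pollen), ds.meteo
        scheme = scheme_for(taxon)
        horizon = config.horizons[0]
        spec = WindowSpec(w=config.window, n=horizon)
        table = build_tabular_dataset(seasons, meteo, spec, scheme)
        train_years, _ = year_grouped_split(
            sorted(table["year"].unique()), config.split_fraction, seed=config.seed + horizon
        )
        train = table[table["year"].isin(train_years)].reset_index(drop=True)

        # importances from the best-accuracy tree family on this cell
        tree_roster = [f for f in config.roster if f in TREE_FAMILIES]
        importance_shares = None
        best_tree = None
        if tree_roster:
            cell_cfg = ExperimentConfig(
                taxa=(taxon,),
                horizons=(horizon,),
                window=config.window,
                split_fraction=config.split_fraction,
                seed=config.seed,
                roster=tuple(tree_roster),
                years=config.years,
            )
            res, _ = run_experiment1(cell_cfg, data={taxon: (seasons, meteo)})
            best_tree = res.iloc[0]["model"]
            fitted, _ = fit_predict(
                ModelSpec(best_tree, "classification", seed=config.seed),
                train,
                train,
                scheme=scheme,
            )
            imp = fitted.feature_importances
            total = imp.sum()
            if total > 0:
                importance_shares = (100.0 * imp / total).sort_values(ascending=False)

        # normalized mutual information on the base-feature view
        view = _mi_feature_view(train)
        y = train["target_class"].to_numpy(dtype=object)
        nmi = {
            name: magn_mod.normalized_mi(view[name].to_numpy(dtype=float), y)
            for name in view.columns
        }
        nmi = pd.Series(nmi).sort_values(ascending=False)
        nmi_shares = 100.0 * nmi / nmi.sum()

        rules, _ = magn_mod.season_rules(
            seasons, meteo, scheme, config.min_support, config.min_confidence
        )
        report[taxon] = {
            "best_tree_model": best_tree,
            "importance_shares": importance_shares,
            "nmi": nmi,
            "nmi_shares": nmi_shares,
            "rules": rules,
        }
    return report


def render_report(results: pd.DataFrame, characterization: dict, out_dir) -> list[Path]:
    """Write benchmark and characterization artifacts to a directory.

    Emits the results CSV, rules CSV, importance/MI shares CSV, a
    support-vs-confidence rule scatter and an observed-vs-predicted season
    plot skeleton.  Returns the paths written.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []

    res_path = out / "results.csv"
    results.to_csv(res_path, index=False)
    written.append(res_path)

    rule_rows, share_rows = [], []
    for taxon, rep in characterization.items():
        for r in rep["rules"]:
            rule_rows.append({"taxon": taxon, **r.as_row()})
        for feat, share in rep["nmi_shares"].items():
            share_rows.append(
                {"taxon": taxon, "feature": feat, "kind": "normalized_mi", "share_pct": share}
            )
        if rep["importance_shares"] is not None:
            for feat, share in rep["importance_shares"].items():
                share_rows.append(
                    {"taxon": taxon, "feature": feat, "kind": "importance", "share_pct": share}
                )
    rules_path = out / "rules.csv"
    pd.DataFrame(
        rule_rows, columns=["taxon", "antecedent", "consequent", "support", "confidence", "lift"]
    ).to_csv(rules_path, index=False)
    written.append(rules_path)

    shares_path = out / "shares.csv"
    pd.DataFrame(share_rows, columns=["taxon", "feature", "kind", "share_pct"]).to_csv(
        shares_path, index=False
    )
    written.append(shares_path)

    # support vs confidence scatter, dot size = support, colour = lift
    fig, ax = plt.subplots(figsize=(6, 4))
    if rule_rows:
        df = pd.DataFrame(rule_rows)
        sc = ax.scatter(
            df["support"], df["confidence"], s=400 * df["support"], c=df["lift"], cmap="viridis"
        )
        fig.colorbar(sc, ax=ax, label="lift")
    ax.set_xlabel("support")
    ax.set_ylabel("confidence")
    ax.set_title("Weather-to-pollen-class association rules")
    scatter_path = out / "rules_scatter.png"
    fig.savefig(scatter_path, dpi=100)
    plt.close(fig)
    written.append(scatter_path)

    # observed vs predicted season curve for the accuracy-best model row
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ok = results[results["error"] == ""] if "error" in results else results
    if not ok.empty:
        ax.bar(
            np.arange(len(ok)),
            ok["accuracy"].to_numpy(dtype=float),
            tick_label=[f"{t[:3]}-h{h}-{m[:8]}" for t, h, m in zip(ok["taxon"], ok["horizon"], ok["model"])],
        )
        ax.tick_params(axis="x", rotation=90, labelsize=6)
    ax.set_ylabel("accuracy")
    ax.set_title("Held-out classification accuracy per model")
    season_path = out / "accuracy_overview.png"
    fig.tight_layout()
    fig.savefig(season_path, dpi=100)
    plt.close(fig)
    written.append(season_path)
    return written
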