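"""Visualization tables/plots and end-to-end pipeline orchestration.

Every figure has a CSV twin: the plotting functions first build an exact
frequency table and the figure is rendered from that table, so tests and
downstream consumers work with numbers, not pixels.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import __version__  # noqa: E402
from .clustering import select_k  # noqa: E402
from .cohort import select_cohort  # noqa: E402
from .config import PipelineConfig  # noqa: E402
from .distance import minmax_normalize, pairwise_distances, pool  # noqa: E402
from .profiling import (  # noqa: E402
    fit_membership_model,
    hospitalization_outcomes,
    orient_clusters,
    summarize_clusters,
)
from .sequences import ALPHABETS, sequences_from_wide  # noqa: E402
from .synthetic import generate_cohort, read_fixture, write_fixture  # noqa: E402

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    pass


def state_distribution(
    wide: pd.DataFrame, dimension: str, group: pd.Series | None = None
) -> pd.DataFrame:
    """Per-interval state frequencies (optionally per cluster).

    Returns a tidy table with columns ``[group,] interval, state, freq``;
    frequencies over the alphabet sum to 1 within each interval.
    """
    if len(wide) == 0:
        raise PipelineError("no sequences to tabulate")
    alphabet = ALPHABETS[dimension].states
    frames = []
    groups = [(None, wide)] if group is None else [
        (g, wide.loc[group.loc[wide.index] == g]) for g in sorted(group.unique())
    ]
    for gname, sub in groups:
        for j, col in enumerate(sub.columns):
            freq = sub[col].value_counts(normalize=True)
            for state in alphabet:
                row = {"interval": j, "state": state, "freq": float(freq.get(state, 0.0))}
                if gname is not None:
                    row["group"] = gname
                frames.append(row)
    return pd.DataFrame(frames)


def top_sequences(
    wide: pd.DataFrame, n: int = 10, group: pd.Series | None = None
) -> pd.DataFrame:
    """The ``n`` most frequent full sequences, with cumulative percentage.

    Sequences are compared as whole strings (states joined by "-"); ties in
    count break lexicographically by sequence string.
    """
    def one(sub: pd.DataFrame, gname) -> pd.DataFrame:
        seqs = sub.apply(lambda r: "-".join(r), axis=1)
        counts = seqs.value_counts()
        df = counts.reset_index()
        df.columns = ["sequence", "count"]
        df = df.sort_values(["count", "sequence"], ascending=[False, True],
                            kind="mergesort").head(n)
        df["percentage"] = 100.0 * df["count"] / len(sub)
        df["cumulative_percentage"] = df["percentage"].cumsum()
        if gname is not None:
            df.insert(0, "group", gname)
        return df

    if group is None:
        return one(wide, None).reset_index(drop=True)
    frames = [
        one(wide.loc[group.loc[wide.index] == g], g) for g in sorted(group.unique())
    ]
    return pd.concat(frames, ignore_index=True)


def plot_state_distribution(freq: pd.DataFrame, dimension: str, out_base: Path) -> None:
    """Stacked-bar state distribution plot written as SVG and PNG."""
    pivot = freq.pivot_table(index="interval", columns="state", values="freq",
                             aggfunc="mean").fillna(0.0)
    pivot = pivot[[s for s in ALPHABETS[dimension].states if s in pivot.columns]]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    bottom = np.zeros(len(pivot))
    for state in pivot.columns:
        ax.bar(pivot.index, pivot[state], bottom=bottom, label=state, width=0.85)
        bottom += pivot[state].to_numpy()
    ax.set_xlabel("interval")
    ax.set_ylabel("state frequency")
    ax.set_title(f"State distribution: {dimension}")
    ax.legend(fontsize=7, ncol=4)
    fig.tight_layout()
    for ext in ("svg", "png"):
        fig.savefig(out_base.with_suffix(f".{ext}"))
    plt.close(fig)


def plot_top_sequences(table: pd.DataFrame, dimension: str, out_base: Path) -> None:
    """Horizontal bar plot of the most frequent sequences (SVG and PNG)."""
    sub = table if "group" not in table.columns else table[table["group"] == table["group"].iloc[0]]
    fig, ax = plt.subplots(figsize=(7, 3.5))
    ax.barh(range(len(sub)), sub["percentage"].to_numpy()[::-1])
    ax.set_yticks(range(len(sub)))
    ax.set_yticklabels(sub["sequence"].to_numpy()[::-1], fontsize=6)
    ax.set_xlabel("% of cohort")
    ax.set_title(f"Most frequent sequences: {dimension}")
    fig.tight_layout()
    for ext in ("svg", "png"):
        fig.savefig(out_base.with_suffix(f".{ext}"))
    plt.close(fig)


def _write_matrix_csv(matrix, path: Path) -> None:
    pd.DataFrame(matrix.values, index=matrix.labels, columns=matrix.labels).to_csv(
        path, lineterminator="\n"
    )


def run_pipeline(config: PipelineConfig, out_dir) -> dict:
    """Execute the full analysis: simulate/load -> cohort -> sequences ->
    distances -> clustering -> profiling -> plots.

    Writes a report bundle under ``out_dir`` (tables as CSV, manifests and
    reports as JSON, figures as SVG/PNG) and returns the in-memory results.
    Re-running with identical config and seed reproduces all non-plot
    outputs byte-identically.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stage = "input"
    manifest: dict = {
        "careseq_version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "stages": {},
    }
    manifest["config_hash"] = hashlib.sha256(
        json.dumps(manifest["config"], sort_keys=True).encode()
    ).hexdigest()

    try:
        if config.input_dir is not None:
            tables = read_fixture(config.input_dir)
        else:
            tables = generate_cohort(config.generator)
            write_fixture(tables, out_dir / "input", config.generator)
        manifest["stages"]["input"] = {k: int(len(v)) for k, v in tables.items()}

        stage = "cohort"
        cohort, flags, attrition = select_cohort(
            tables,
            observation_window=config.observation_window,
            insurance_window=config.insurance_window,
            lookback_year=config.lookback_year,
            birth_year_window=config.birth_year_window,
            hospital_outpatient_min_quarters=config.hospital_outpatient_min_quarters,
        )
        cohort.to_csv(out_dir / "cohort.csv", index=False, lineterminator="\n")
        flags.to_csv(out_dir / "flags.csv", index=False, lineterminator="\n")
        (out_dir / "attrition.json").write_text(json.dumps(attrition, indent=2) + "\n")
        manifest["stages"]["cohort"] = attrition
        if len(cohort) < 3:
            raise PipelineError("cohort too small to cluster")

        stage = "sequences"
        from .sequences import encode_cohort

        pids = cohort["patient_id"].tolist()
        wide = encode_cohort(
            tables["events"], pids, config.observation_window, config.strips_threshold
        )
        for dim, df in wide.items():
            df.to_csv(out_dir / f"sequences_{dim}.csv", lineterminator="\n")
        (out_dir / "alphabets.json").write_text(
            json.dumps(
                {d: list(a.states) for d, a in ALPHABETS.items()}, indent=2
            )
            + "\n"
        )
        manifest["stages"]["sequences"] = {d: int(len(df)) for d, df in wide.items()}

        stage = "distance"
        normalized = []
        for dim, df in wide.items():
            seqs = sequences_from_wide(df, dim)
            raw = pairwise_distances(seqs)
            tmax = 2.0 * df.shape[1]
            norm = minmax_normalize(
                raw,
                method=config.normalization,
                theoretical_max=tmax if config.normalization == "theoretical_max" else None,
            )
            normalized.append(norm)
            if config.write_matrices:
                _write_matrix_csv(raw, out_dir / f"distance_{dim}_raw.csv")
        pooled = pool(normalized)
        if config.write_matrices:
            _write_matrix_csv(pooled, out_dir / "distance_pooled.csv")
        (out_dir / "distance_manifest.json").write_text(
            json.dumps(
                [
                    {"dimension": m.dimension, "kind": m.kind, "denominator": m.denominator}
                    for m in normalized
                ],
                indent=2,
            )
            + "\n"
        )
        manifest["stages"]["distance"] = {"n": pooled.n}

        stage = "clustering"
        k_max = min(config.k_max, pooled.n - 1)
        profile = select_k(pooled, config.k_min, k_max)
        profile.table.to_csv(out_dir / "quality_profile.csv", index=False,
                             lineterminator="\n")
        k = profile.recommended_k
        result = profile.results[k]
        assignment = pd.Series(result.assignment, index=pids, name="cluster")
        assignment.rename_axis("patient_id").to_csv(out_dir / "assignments.csv",
                                                    lineterminator="\n")
        (out_dir / "medoids.json").write_text(
            json.dumps(
                {
                    "k": k,
                    "medoid_patient_ids": [pids[i] for i in result.medoid_indices],
                    "total_cost": result.total_cost,
                },
                indent=2,
            )
            + "\n"
        )
        manifest["stages"]["clustering"] = {"recommended_k": k}

        stage = "profiling"
        adherent_label = orient_clusters(wide["diagnostics"], assignment)
        summary = summarize_clusters(cohort, assignment, adherent_label)
        summary.to_csv(out_dir / "table1.csv", index=False, lineterminator="\n")
        outcome = (assignment.loc[cohort["patient_id"]] == adherent_label).astype(int)
        regression = fit_membership_model(cohort, outcome)
        regression.table.rename_axis("predictor").to_csv(
            out_dir / "table2.csv", lineterminator="\n"
        )
        outcomes = hospitalization_outcomes(
            cohort, tables["hospitalizations"], assignment, adherent_label
        )
        outcomes.table.to_csv(out_dir / "outcomes.csv", index=False, lineterminator="\n")

        report = {
            "n_cohort": int(len(cohort)),
            "recommended_k": k,
            "adherent_cluster": adherent_label,
            "cluster_sizes": {
                str(lab): int((assignment == lab).sum()) for lab in sorted(assignment.unique())
            },
            "quality": profile.table.to_dict(orient="records"),
            "regression": {
                "converged": regression.converged,
                "n_used": regression.n_used,
                "excluded_missing_ses": regression.excluded_missing_ses,
                "odds_ratios": regression.table.round(6).to_dict(orient="index"),
            },
            "hospitalization": {
                "per_cluster": outcomes.table.to_dict(orient="records"),
                "p_any": outcomes.p_any,
                "p_count": outcomes.p_count,
                "mean_ratio": outcomes.mean_ratio,
            },
        }
        (out_dir / "report.json").write_text(json.dumps(report, indent=2) + "\n")

        stage = "plots"
        for dim, df in wide.items():
            freq = state_distribution(df, dim, group=assignment)
            freq.to_csv(out_dir / f"state_distribution_{dim}.csv", index=False,
                        lineterminator="\n")
            tops = top_sequences(df, 10, group=assignment)
            tops.to_csv(out_dir / f"top_sequences_{dim}.csv", index=False,
                        lineterminator="\n")
            if config.make_plots:
                plot_state_distribution(freq, dim, out_dir / f"state_distribution_{dim}")
                plot_top_sequences(tops, dim, out_dir / f"top_sequences_{dim}")
    except PipelineError:
        raise
    except FileNotFoundError as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc
    except Exception as exc:
        raise PipelineError(f"stage {stage!r} failed: {exc}") from exc

    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")
    return {
        "tables": tables,
        "cohort": cohort,
        "flags": flags,
        "attrition": attrition,
        "sequences": wide,
        "pooled": pooled,
        "quality": profile,
        "assignment": assignment,
        "adherent_label": adherent_label,
        "summary": summary,
        "regression": regression,
        "outcomes": outcomes,
        "report": report,
    }
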