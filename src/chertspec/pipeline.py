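"""End-to-end analysis orchestration.

`run_full_analysis` chains every stage — preprocessing, chemometric ratios
and group tests, PCA with the compositional sanity check, K-means with
truth-matched accuracy, cluster mean spectra with variability envelopes,
canonical variates analysis with passive projection of unknowns, and the
supervised protocol — writes each artifact as a delimited text table under
the output directory, and returns the in-memory bundle.  A MANIFEST lists
which artifacts completed; the run log records every parameter and seed so
a run can be replayed exactly.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import bands as _bands
from .chemometrics import compare_all_ratios, ratio_table
from .classify import run_supervised_protocol
from .io import SpectrumSet
from .multivariate import (
    abundance_sanity_check,
    cluster_vs_truth,
    discriminant_analysis,
    kmeans,
    pca,
)
from .preprocess import PreprocessConfig, preprocess_pipeline, savgol_derivative
from .synthetic import AssemblageConfig, generate_assemblage


@dataclass
class RunConfig:
    """Configuration of a full run.

    Exactly one input source: either `spectrum_set` (loaded data) or
    `simulate` (an AssemblageConfig).  `passive_labels` marks groups that
    are projected passively in the ordination and treated as unknowns by
    the classifiers.
    """

    spectrum_set: SpectrumSet | None = None
    simulate: AssemblageConfig | None = None
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)
    run_ratios: bool = True
    run_pca: bool = True
    run_kmeans: bool = True
    run_cva: bool = True
    run_classify: bool = True
    passive_labels: tuple[str, ...] = ("unknown",)
    kmeans_k: int = 2
    pca_components: int = 6
    seed: int = 0
    output_dir: str | Path | None = None

    def __post_init__(self):
        if (self.spectrum_set is None) == (self.simulate is None):
            raise ValueError("exactly one of spectrum_set / simulate must be given")


def _write(df: pd.DataFrame, out: Path | None, name: str, manifest: list[str]) -> None:
    if out is not None:
        df.to_csv(out / f"{name}.csv", float_format="%.12g")
    manifest.append(name)


def cluster_envelopes(matrix: pd.DataFrame, assignments: pd.Series) -> pd.DataFrame:
    """Pointwise mean / min / max spectrum per cluster (long format)."""
    rows = []
    for c in sorted(assignments.unique()):
        block = matrix.loc[assignments.index[assignments == c]]
        rows.append(pd.DataFrame({
            "cluster": c,
            "wavenumber": matrix.columns.astype(float),
            "mean": block.mean(axis=0).to_numpy(),
            "min": block.min(axis=0).to_numpy(),
            "max": block.max(axis=0).to_numpy(),
        }))
    return pd.concat(rows, ignore_index=True)


def run_full_analysis(cfg: RunConfig) -> dict:
    """Execute the configured stages; returns the report bundle.

    Bundle keys (when toggled on): ``matrix``, ``anchor_reports``,
    ``ratios``, ``group_comparisons``, ``pca_scores``, ``pca_loadings``,
    ``pca_variance``, ``sanity_check``, ``kmeans``, ``cluster_accuracy``,
    ``cluster_envelopes``, ``second_derivative_means``, ``cva``,
    ``classifier``, ``truth`` (synthetic runs), ``log``.
    """
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    manifest: list[str] = []
    log: dict = {
        "started": _dt.datetime.now().isoformat(timespec="seconds"),
        "seed": cfg.seed,
        "preprocess": cfg.preprocess.to_dict(),
        "stages": [],
    }
    bundle: dict = {"log": log}
    try:
        if cfg.simulate is not None:
            sim = cfg.simulate
            sset, truth = generate_assemblage(sim)
            bundle["truth"] = truth
            _write(truth, out, "truth", manifest)
            log["input"] = {"source": "simulate", "seed": sim.seed,
                            "n_per_group": dict(sim.n_per_group)}
        else:
            sset = cfg.spectrum_set
            log["input"] = {"source": "spectrum_set",
                            "provenance": sset.provenance}

        log["stages"].append("preprocess")
        matrix, segs, reports = preprocess_pipeline(sset, cfg.preprocess)
        bundle["matrix"] = matrix
        bundle["anchor_reports"] = pd.DataFrame(reports).set_index("specimen_id")
        _write(matrix, out, "feature_matrix", manifest)
        _write(bundle["anchor_reports"], out, "anchor_reports", manifest)

        labels = pd.Series(sset.groups(), index=sset.specimen_ids, name="group")
        labelled = labels.dropna()[~labels.dropna().isin(cfg.passive_labels)]

        if cfg.run_ratios:
            log["stages"].append("ratios")
            ratios = ratio_table(segs)
            bundle["ratios"] = ratios
            _write(ratios, out, "ratios", manifest)
            if labelled.nunique() == 2:
                comps = compare_all_ratios(ratios)
                bundle["group_comparisons"] = comps
                _write(comps.set_index("ratio"), out, "group_comparisons", manifest)

        if cfg.run_pca:
            log["stages"].append("pca")
            p = pca(matrix, n_components=cfg.pca_components)
            bundle["pca_scores"] = p.scores
            bundle["pca_loadings"] = p.loadings
            bundle["pca_variance"] = pd.Series(
                p.explained_variance_fraction,
                index=p.scores.columns, name="explained_variance_fraction",
            )
            _write(p.scores, out, "pca_scores", manifest)
            _write(p.loadings, out, "pca_loadings", manifest)
            _write(bundle["pca_variance"].to_frame(), out, "pca_variance", manifest)
            if cfg.run_ratios:
                bundle["sanity_check"] = abundance_sanity_check(p, bundle["ratios"])
                if out is not None:
                    (out / "sanity_check.json").write_text(
                        json.dumps(bundle["sanity_check"], indent=2, default=str)
                    )
                manifest.append("sanity_check")

        if cfg.run_kmeans:
            log["stages"].append("kmeans")
            km = kmeans(matrix, k=cfg.kmeans_k, seed=cfg.seed)
            bundle["kmeans"] = km
            _write(km.assignments.to_frame(), out, "kmeans_assignments", manifest)
            if labelled.nunique() >= 2:
                acc, wrong = cluster_vs_truth(
                    km.assignments.loc[labelled.index], labelled
                )
                bundle["cluster_accuracy"] = {"accuracy": acc, "misassigned": wrong}
                manifest.append("cluster_accuracy")
                if out is not None:
                    (out / "cluster_accuracy.json").write_text(
                        json.dumps(bundle["cluster_accuracy"], indent=2)
                    )
            env = cluster_envelopes(matrix, km.assignments)
            bundle["cluster_envelopes"] = env
            _write(env.set_index("cluster"), out, "cluster_envelopes", manifest)

        if labelled.nunique() >= 2:
            # second-derivative domain-average spectra (band-assignment aid)
            sd_rows = {}
            for g in sorted(labelled.unique()):
                block = [s for s in segs if s.specimen_id in set(labelled[labelled == g].index)]
                ders = [savgol_derivative(s, cfg.preprocess.sg_window,
                                          cfg.preprocess.sg_polyorder, 2)
                        for s in block]
                sd_rows[g] = np.mean([d.concatenated()[1] for d in ders], axis=0)
            sd = pd.DataFrame(sd_rows, index=matrix.columns).T
            bundle["second_derivative_means"] = sd
            _write(sd, out, "second_derivative_means", manifest)

        if cfg.run_cva and labelled.nunique() >= 2:
            log["stages"].append("cva")
            bm = _bands.band_matrix(segs)
            passive = [sid for sid, g in labels.items()
                       if g in cfg.passive_labels or pd.isna(g)]
            cva = discriminant_analysis(bm, labels.to_dict(), passive_ids=passive)
            bundle["cva"] = cva
            _write(cva.scores, out, "cva_scores", manifest)
            _write(cva.passive_scores, out, "cva_passive_scores", manifest)
            _write(cva.coefficients, out, "cva_coefficients", manifest)

        if cfg.run_classify and labelled.nunique() == 2:
            log["stages"].append("classify")
            rep = run_supervised_protocol(
                matrix, labels, seed=cfg.seed,
                exclude_labels=cfg.passive_labels,
            )
            bundle["classifier"] = rep
            _write(rep.loo, out, "classifier_loo", manifest)
            _write(rep.test, out, "classifier_test", manifest)
            if rep.unknown_predictions is not None:
                _write(rep.unknown_predictions, out, "unknown_predictions", manifest)
    except Exception as e:
        log["failed_stage"] = log["stages"][-1] if log["stages"] else "input"
        if out is not None:
            (out / "MANIFEST").write_text(
                "\n".join(manifest) + f"\nINCOMPLETE: failed at {log['failed_stage']}\n"
            )
        raise
    log["finished"] = _dt.datetime.now().isoformat(timespec="seconds")
    if out is not None:
        (out / "MANIFEST").write_text("\n".join(manifest) + "\nCOMPLETE\n")
        (out / "run_log.json").write_text(json.dumps(log, indent=2, default=str))
    return bundle


def deposited_benchmark(
    data_dir: str | Path,
    metadata_table: str | Path | None = None,
    mode: str = "peak_max",
) -> dict:
    """Benchmark checks against a locally downloaded copy of the publicly
    deposited Rhynie chert raw spectra (Edinburgh DataShare,
    DOI 10.7488/ds/3806).

    `data_dir` must contain one two-column CSV per specimen plus (unless
    given separately) a metadata.csv with specimen_id/group columns.
    Returns PCA variance fractions and the methyl/methylene ratio summary
    (group means, range) so they can be compared with the published values.
    Requires the data on disk; nothing is downloaded.
    """
    from .chemometrics import compare_groups
    from .io import read_spectra

    data_dir = Path(data_dir)
    files = sorted(p for p in data_dir.glob("*.csv") if p.name != "metadata.csv")
    if not files:
        raise FileNotFoundError(
            f"no spectrum CSVs in {data_dir}; download the deposited raw "
            f"spectra (DOI 10.7488/ds/3806) and export them as two-column CSVs"
        )
    meta = metadata_table or (data_dir / "metadata.csv")
    sset = read_spectra(files, format="csv", metadata_table=meta)
    matrix, segs, _ = preprocess_pipeline(sset)
    p = pca(matrix, n_components=6)
    ratios = ratio_table(segs, mode=mode)
    cmp = compare_groups(ratios, "R32")
    return {
        "pca_variance_fractions": p.explained_variance_fraction.tolist(),
        "pca_cumulative_6": float(p.explained_variance_fraction.sum()),
        "r32_mean_prokaryote": cmp.mean1,
        "r32_mean_eukaryote": cmp.mean2,
        "r32_range": (float(ratios["R32"].min()), float(ratios["R32"].max())),
        "r32_mannwhitney_p": cmp.p_value,
    }
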