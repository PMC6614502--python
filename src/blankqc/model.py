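"""Top-level modelling interface.

:class:`BatchConditioning` is built from a peak table (read from files or
simulated) and orchestrates the full analysis when fitted; the returned
:class:`BatchConditioningResults` carries the corrected table, per-feature
drift fits, feature classification, conditioning curves, blank PCA and
profile clusters, with ``summary()`` for a console overview and ``save()``
for the TSV result bundle.

    model = BatchConditioning.from_simulation(plasma_like(seed=1))
    res = model.fit(m=200, seed=1)
    print(res.summary())
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import cluster as _cluster
from . import screen as _screen
from . import stats as _stats
from . import svrc as _svrc
from .config import PipelineConfig
from .io import PeakTable, read_peak_table, write_results
from .simulate import SimulationConfig, SyntheticTruth, generate_batch

__all__ = ["BatchConditioning", "BatchConditioningResults"]

log = logging.getLogger("blankqc")


class BatchConditioning:
    """Blank-injection conditioning model for one LC-MS batch.

    Parameters
    ----------
    table : PeakTable
        Annotated peak table (areas, RT, width, detection, sequence).
    config : PipelineConfig, optional
        Stage parameters; defaults to the method's standard constants.
    truth : SyntheticTruth, optional
        Planted ground truth when the table was simulated (carried through
        to the results for validation studies).
    """

    def __init__(self, table: PeakTable, config: PipelineConfig | None = None,
                 truth: SyntheticTruth | None = None):
        self.table = table.validate()
        self.config = config or PipelineConfig()
        self.truth = truth

    @classmethod
    def from_files(cls, table_path, sequence_path, detection_path=None,
                   config: PipelineConfig | None = None) -> "BatchConditioning":
        table = read_peak_table(table_path, sequence_path, detection_path)
        return cls(table, config=config)

    @classmethod
    def from_simulation(cls, sim: SimulationConfig,
                        config: PipelineConfig | None = None) -> "BatchConditioning":
        table, truth = generate_batch(sim)
        if config is None:
            config = PipelineConfig(simulate=sim)
        return cls(table, config=config, truth=truth)

    # ------------------------------------------------------------------
    def fit(self, m: int | None = None, seed: int | None = None,
            cluster_curves: bool = True) -> "BatchConditioningResults":
        """Run correction, screening, conditioning assessment and clustering.

        ``m`` and ``seed`` override the permutation settings in the config.
        """
        cfg = self.config
        m = cfg.gpca.m if m is None else m
        seed = cfg.gpca.seed if seed is None else seed

        log.info("stage correct: %d features, %d injections",
                 self.table.n_features, self.table.n_injections)
        corrected, fits = _svrc.correct_table(
            self.table,
            j=cfg.svrc.reference_j,
            n_eps=cfg.svrc.n_eps,
            n_gamma=cfg.svrc.n_gamma,
            trend_floor_frac=cfg.svrc.trend_floor_frac,
        )

        log.info("stage screen")
        classification = _screen.screen_table(
            corrected,
            match_fraction=cfg.screen.match_fraction,
            blank_ratio_threshold=cfg.screen.blank_ratio,
            coverage_threshold=cfg.screen.coverage,
            qc_rsd_threshold=cfg.screen.qc_rsd,
            include_qc_as_samples=cfg.screen.include_qc_as_samples,
            reference_j=cfg.svrc.reference_j,
        )
        informative = classification.index[classification["label"] == "informative"]
        uninformative = classification.index.difference(informative)
        log.info("screen: %d informative / %d features",
                 len(informative), len(classification))

        blank_scores = blank_loadings = blank_varfrac = None
        seq = self.table.sequence
        n_blanks = (seq["sample_class"] == "blank").sum()
        if n_blanks >= 3 and len(uninformative) >= 2:
            try:
                blank_scores, blank_loadings, blank_varfrac = _stats.blank_pca(
                    corrected, uninformative
                )
            except ValueError as exc:
                log.warning("blank PCA skipped: %s", exc)

        inf_table = corrected.subset_features(informative)
        curves, delta_results = {}, {}
        for ctype in ("intense", "mild"):
            n_cycles = seq.loc[seq["cycle_type"] == ctype, "cycle_id"].nunique()
            if n_cycles < 2 or len(informative) == 0:
                continue
            log.info("stage assess (%s): m=%d", ctype, m)
            curve, dres = _stats.conditioning_curve(
                inf_table, ctype,
                reference_position=cfg.gpca.reference_position,
                m=m, seed=seed, alpha=cfg.gpca.fdr_alpha,
            )
            curves[ctype], delta_results[ctype] = curve, dres

        profiles = normalized = labels = linkage_Z = None
        summary_df = median_profiles = None
        cluster_curve_frames: dict = {}
        profile_type = "intense" if "intense" in curves else (
            "mild" if "mild" in curves else None)
        if profile_type is not None and len(informative) >= cfg.clustering.k:
            log.info("stage cluster (%s cycles)", profile_type)
            profiles, normalized, constant_ids = _cluster.build_profiles(
                inf_table, profile_type
            )
            if len(normalized) >= cfg.clustering.k:
                labels, linkage_Z = _cluster.hca_pearson(
                    normalized, k=cfg.clustering.k,
                    method=cfg.clustering.linkage,
                    rt_median=inf_table.features["rt_median"],
                )
                summary_df, median_profiles = _cluster.cluster_summary(
                    labels, inf_table.features, normalized
                )
                if cluster_curves:
                    for lab in sorted(labels.unique()):
                        ids = labels.index[labels == lab]
                        if len(ids) < 2:
                            continue
                        sub = inf_table.subset_features(ids)
                        curve, _ = _stats.conditioning_curve(
                            sub, profile_type,
                            reference_position=cfg.gpca.reference_position,
                            m=m, seed=seed, alpha=cfg.gpca.fdr_alpha,
                        )
                        cluster_curve_frames[lab] = curve

        return BatchConditioningResults(
            model=self,
            corrected=corrected,
            svrc_fits=fits,
            classification=classification,
            curves=curves,
            delta_results=delta_results,
            blank_scores=blank_scores,
            blank_loadings=blank_loadings,
            blank_varfrac=blank_varfrac,
            profiles=profiles,
            normalized_profiles=normalized,
            cluster_labels=labels,
            linkage=linkage_Z,
            cluster_table=summary_df,
            median_profiles=median_profiles,
            cluster_curves=cluster_curve_frames,
            m=m,
            seed=seed,
        )


@dataclass
class BatchConditioningResults:
    """Fitted results bundle; see :class:`BatchConditioning`."""

    model: BatchConditioning
    corrected: PeakTable
    svrc_fits: list
    classification: pd.DataFrame
    curves: dict
    delta_results: dict
    blank_scores: pd.DataFrame | None
    blank_loadings: pd.DataFrame | None
    blank_varfrac: np.ndarray | None
    profiles: pd.DataFrame | None
    normalized_profiles: pd.DataFrame | None
    cluster_labels: pd.Series | None
    linkage: np.ndarray | None
    cluster_table: pd.DataFrame | None
    median_profiles: pd.DataFrame | None
    cluster_curves: dict = field(default_factory=dict)
    m: int = 0
    seed: int = 0

    # -- derived quantities -------------------------------------------
    @property
    def class_counts(self) -> pd.Series:
        return self.classification["label"].value_counts().reindex(
            _screen.LABELS, fill_value=0
        )

    @property
    def informative_ids(self) -> pd.Index:
        return self.classification.index[self.classification["label"] == "informative"]

    def qc_rsd(self, corrected: bool = True) -> pd.Series:
        """Per-feature %RSD over the reference injections."""
        table = self.corrected if corrected else self.model.table
        refs = _svrc.reference_orders(table, j=self.model.config.svrc.reference_j)
        return table.area[refs].apply(_svrc.rsd, axis=1)

    def recovery_position(self, cycle_type: str = "intense",
                          metric: str = "area") -> int | None:
        """Smallest position n from which the significant-feature count
        stays at the false-positive level (<= alpha x n informative) for
        all later positions; None if the last position is still above."""
        if cycle_type not in self.curves:
            return None
        curve = self.curves[cycle_type].sort_values("position_n")
        thresh = self.model.config.gpca.fdr_alpha * max(len(self.informative_ids), 1)
        above = curve[f"n_sig_{metric}"].to_numpy() > thresh
        if above.any():
            last_bad = int(np.flatnonzero(above)[-1])
            if last_bad == len(curve) - 1:
                return None
            return int(curve["position_n"].iloc[last_bad + 1])
        return int(curve["position_n"].iloc[0])

    # -- presentation --------------------------------------------------
    def summary(self) -> str:
        lines = []
        w = 64
        lines.append("Blank-injection conditioning analysis".center(w))
        lines.append("=" * w)
        t = self.model.table
        lines.append(f"Injections: {t.n_injections}   Features: {t.n_features}   "
                     f"Permutations m: {self.m}   Seed: {self.seed}")
        counts = self.class_counts
        lines.append("Feature classification:")
        for lab, n in counts.items():
            lines.append(f"  {lab:<14} {n:>6}")
        rsd_raw = self.qc_rsd(corrected=False).median()
        rsd_cor = self.qc_rsd(corrected=True).median()
        lines.append(f"Median QC RSD: {rsd_raw:.2f}% raw -> {rsd_cor:.2f}% corrected")
        for ctype, curve in self.curves.items():
            lines.append("-" * w)
            lines.append(f"Conditioning curve ({ctype} deconditioning), "
                         f"reference position {self.model.config.gpca.reference_position}:")
            lines.append(f"  {'n':>2} {'delta':>7} {'p':>7} "
                         f"{'#area':>6} {'#RT':>6} {'#width':>6}")
            for _, r in curve.iterrows():
                star = "*" if r["p_value"] < 0.05 else " "
                lines.append(
                    f"  {int(r['position_n']):>2} {r['delta']:>7.3f} "
                    f"{r['p_value']:>6.3f}{star} {int(r['n_sig_area']):>6} "
                    f"{int(r['n_sig_rt']):>6} {int(r['n_sig_width']):>6}"
                )
            rec = self.recovery_position(ctype)
            lines.append(f"  recovery (area count at false-positive level): "
                         f"position {rec if rec is not None else '>7'}")
        if self.cluster_table is not None:
            lines.append("-" * w)
            lines.append("Profile clusters (HCA, 1 - Pearson, "
                         f"{self.model.config.clustering.linkage} linkage):")
            for lab, r in self.cluster_table.iterrows():
                lines.append(
                    f"  cluster {lab}: {int(r['n_members'])} features "
                    f"({100 * r['fraction']:.1f}%), median RT {r['rt_median']:.2f} min"
                )
        lines.append("=" * w)
        return "\n".join(lines)

    def save(self, out_dir, meta: dict | None = None) -> dict:
        """Write the result bundle as TSVs (classification, fits, curves,
        clusters, blank PCA) with run-metadata headers."""
        meta = dict(meta or {})
        meta.setdefault("seed", self.seed)
        meta.setdefault("m", self.m)
        tables = {"classification": self.classification,
                  "svrc_fits": _svrc.fits_frame(self.svrc_fits)}
        for ctype, curve in self.curves.items():
            tables[f"curve_{ctype}"] = curve
        for lab, curve in self.cluster_curves.items():
            tables[f"curve_cluster{lab}"] = curve
        if self.blank_scores is not None:
            tables["blank_pca_scores"] = self.blank_scores
            tables["blank_pca_loadings"] = self.blank_loadings
        if self.cluster_labels is not None:
            tables["cluster_labels"] = self.cluster_labels.to_frame()
            tables["cluster_summary"] = self.cluster_table.reset_index()
            tables["median_profiles"] = self.median_profiles.reset_index()
        paths = write_results(tables, out_dir, meta)
        if self.linkage is not None:
            from pathlib import Path

            newick = _cluster.linkage_newick(
                self.linkage, self.normalized_profiles.index
            )
            p = Path(out_dir) / "dendrogram.nwk"
            p.write_text(newick + "\n")
            paths["dendrogram"] = p
            lz = pd.DataFrame(self.linkage,
                              columns=["child_a", "child_b", "distance", "size"])
            paths.update(write_results({"linkage_matrix": lz}, out_dir, meta))
        return paths
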