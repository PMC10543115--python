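"""Whole-study model object: cohort in, fitted group comparison out.

``ConnectomeStudy`` holds a cohort of per-subject connectivity matrices and
their metadata; ``fit()`` runs the full analysis — network construction,
weighted graph metrics, modular decomposition and hub classification, group
statistics with FDR control, FA partial correlations, and the nodal-feature
classification — and returns a ``StudyResults`` carrying tidy tables and a
``summary()`` report, in the spirit of a statsmodels model/results pair.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import classify as clf
from . import community as comm
from . import construct, metrics
from . import stats as st
from .connectome import Connectome
from .simulate import CohortSpec, SubjectRecord, generate_cohort, read_cohort

__all__ = ["ConnectomeStudy", "StudyResults"]

GLOBAL_METRICS = ("clustering", "path_length", "modularity", "density")
NODAL_METRICS = ("clustering", "within_module_degree", "participation")
DEFAULT_COVARIATES = ("pma_scan", "head_circumference", "n_embryos")


@dataclass
class StudyResults:
    """Container for all fitted tables; see the attributes' docstrings below.

    Attributes
    ----------
    global_table : per-subject global metrics (one row per scan).
    nodal : dict metric -> (subjects x nodes) DataFrame.
    partitions : dict subject_id -> module assignment array.
    hub_classes : dict subject_id -> per-node class array.
    hub_counts : per-subject provincial/connector counts.
    hub_prevalence : per group per node per class prevalence table.
    global_comparisons : tidy StatResult table for the global metrics.
    nodal_comparisons : tidy per-node StatResult table (FDR within each
        metric x contrast family of n_nodes tests).
    hub_count_comparisons : hub-count contrasts.
    asymmetry : left-vs-right paired tests per group and metric.
    fa_correlations : partial correlations of FA with clustering and path
        length in the longitudinal and cross-sectional cohorts.
    classification : dict scheme -> ClassifierReport for PB-TEA vs TB.
    feature_projection : per-subject first-PC coordinates per metric block.
    """

    node_labels: list[str]
    global_table: pd.DataFrame
    nodal: dict[str, pd.DataFrame]
    partitions: dict[str, np.ndarray]
    hub_classes: dict[str, np.ndarray]
    hub_counts: pd.DataFrame
    hub_prevalence: pd.DataFrame
    global_comparisons: pd.DataFrame
    nodal_comparisons: pd.DataFrame
    hub_count_comparisons: pd.DataFrame
    asymmetry: pd.DataFrame
    fa_correlations: pd.DataFrame
    classification: dict[str, clf.ClassifierReport] = field(default_factory=dict)
    feature_projection: pd.DataFrame | None = None

    def significant_nodes(self, metric: str, contrast: str) -> list[int]:
        t = self.nodal_comparisons
        sel = t[(t.metric == metric) & (t.contrast == contrast) & t.significant]
        return sel.node.tolist()

    def summary(self) -> str:
        lines = ["Neonatal connectome study results", "=" * 34, ""]
        g = self.global_table
        lines.append("Group means (global metrics):")
        means = g.groupby("group")[list(GLOBAL_METRICS)].mean()
        lines.append(means.round(4).to_string())
        lines.append("")
        lines.append("Global contrasts (paired t for PB-AB vs PB-TEA; ANCOVA for PB-TEA vs TB):")
        cols = ["contrast", "metric", "effect", "statistic", "p", "q", "significant"]
        lines.append(self.global_comparisons[cols].round(4).to_string(index=False))
        lines.append("")
        nodal_sig = (self.nodal_comparisons.groupby(["contrast", "metric"])["significant"]
                     .sum().rename("n_significant_nodes"))
        lines.append("Significant nodes after FDR (q = 0.05):")
        lines.append(nodal_sig.to_string())
        lines.append("")
        lines.append("Hub count contrasts:")
        lines.append(self.hub_count_comparisons[cols].round(4).to_string(index=False))
        lines.append("")
        lines.append("Hemispheric asymmetry (paired t, left minus right):")
        acols = ["group", "metric", "effect", "statistic", "p", "q", "significant"]
        lines.append(self.asymmetry[acols].round(4).to_string(index=False))
        lines.append("")
        lines.append("FA partial correlations (covariate-adjusted):")
        lines.append(self.fa_correlations.round(4).to_string(index=False))
        if self.classification:
            lines.append("")
            lines.append("PB-TEA vs TB classification:")
            for scheme, rep in self.classification.items():
                row = (f"  {scheme}: accuracy={rep.accuracy:.4f} "
                       f"sensitivity={rep.sensitivity:.4f} specificity={rep.specificity:.4f} "
                       f"AUC={rep.auc:.4f}")
                if rep.ci_high is not None:
                    row += (f" | chance 5-95% CI=[{rep.ci_low:.4f}, {rep.ci_high:.4f}]"
                            f" significant={rep.significant}")
                lines.append(row)
        return "\n".join(lines)


def _result_row(res: st.StatResult, **keys) -> dict:
    return dict(keys, effect=res.effect, statistic=res.statistic, p=res.p,
                q=res.q, significant=res.significant)


class ConnectomeStudy:
    """The three-group neonatal connectome analysis, as a fittable model.

    Parameters
    ----------
    connectomes, records : aligned cohort data.
    prune_fraction : weakest-edge fraction discarded after fractional
        scaling (default 0.05).
    covariates : metadata columns entering the ANCOVA and the partial
        correlations (default age at scan, head circumference, number of
        gestation embryos).
    include_motion : add head motion as an extra covariate.
    """

    def __init__(self, connectomes: list[Connectome], records: list[SubjectRecord],
                 prune_fraction: float = 0.05,
                 covariates: tuple[str, ...] = DEFAULT_COVARIATES,
                 include_motion: bool = False) -> None:
        if len(connectomes) != len(records):
            raise ValueError("connectomes and records must be aligned")
        self.connectomes = connectomes
        self.records = records
        self.prune_fraction = prune_fraction
        self.covariates = tuple(covariates) + (("motion",) if include_motion else ())
        self.meta = pd.DataFrame([vars(r) for r in records]).set_index("subject_id", drop=False)

    # ------------------------------------------------------------------ #
    @classmethod
    def from_simulation(cls, spec: CohortSpec | None = None, **kwargs) -> "ConnectomeStudy":
        spec = spec or CohortSpec()
        connectomes, records = generate_cohort(spec)
        return cls(connectomes, records, **kwargs)

    @classmethod
    def from_directory(cls, path: str | Path, **kwargs) -> "ConnectomeStudy":
        connectomes, records = read_cohort(path)
        return cls(connectomes, records, **kwargs)

    # ------------------------------------------------------------------ #
    def _prepared(self) -> dict[str, np.ndarray]:
        """Fractionally scaled and pruned weights per subject."""
        out = {}
        for c in self.connectomes:
            W = construct.fractional_scale(c.weights)
            out[c.subject_id] = construct.prune_weakest(W, self.prune_fraction)
        return out

    def _covariate_matrix(self, subject_ids) -> np.ndarray:
        """Covariate columns for the given scans; constant columns (e.g. a
        cohort with no twins) are dropped rather than breaking the OLS."""
        C = self.meta.loc[subject_ids, list(self.covariates)].astype(float).to_numpy()
        keep = C.std(axis=0) > 0
        return C[:, keep]

    def _pairs(self) -> pd.DataFrame:
        """Aligned (PB-AB, PB-TEA, TB) subject ids per pair_id."""
        m = self.meta
        ab = m[m.group == "PB-AB"].set_index("pair_id").subject_id
        tea = m[m.group == "PB-TEA"].set_index("pair_id").subject_id
        tb = m[m.group == "TB"].set_index("pair_id").subject_id
        pairs = pd.DataFrame({"ab": ab, "tea": tea}).dropna()
        pairs["tb"] = tb.reindex(pairs.index)
        return pairs

    def binary_comparisons(self, sparsities: tuple[float, ...] = (0.10, 0.15, 0.20, 0.25),
                           q_level: float = 0.05) -> pd.DataFrame:
        """Group contrasts of binary clustering and path length across
        sparsity thresholds (robustness analysis): the strongest
        ``sparsity`` fraction of links is kept as 1-edges, metrics are
        recomputed, and the same paired-t / ANCOVA contrasts are applied
        per sparsity with FDR within each (sparsity, contrast) family."""
        prepared = self._prepared()
        meta = self.meta
        pairs = self._pairs()
        out = []
        for s in sparsities:
            tbl = {}
            for sid, W in prepared.items():
                B = construct.binarize_at_sparsity(W, s)
                _, cb = metrics.binary_clustering(B)
                _, lb = metrics.shortest_path_lengths(B)
                tbl[sid] = {"clustering": cb, "path_length": lb}
            tbl = pd.DataFrame(tbl).T
            cov_sel = meta[meta.group.isin(["PB-TEA", "TB"])].subject_id
            covm = self._covariate_matrix(cov_sel)
            rows = []
            for m in ("clustering", "path_length"):
                res = st.paired_t(tbl.loc[pairs.ab, m].to_numpy(),
                                  tbl.loc[pairs.tea, m].to_numpy())
                rows.append(_result_row(res, sparsity=s, contrast="PB-AB vs PB-TEA",
                                        metric=m, test="paired_t"))
                res = st.ancova_group_effect(tbl.loc[cov_sel, m].to_numpy(),
                                             meta.loc[cov_sel, "group"].to_numpy(), covm)
                rows.append(_result_row(res, sparsity=s, contrast="PB-TEA vs TB",
                                        metric=m, test="ancova"))
            df = pd.DataFrame(rows)
            for contrast, sub in df.groupby("contrast"):
                rej, q = st.fdr_bh(sub.p.to_numpy(), q_level=q_level)
                out.append(sub.assign(q=q, significant=rej))
        return pd.concat(out, ignore_index=True)

    def fit(self, seed: int = 0, partition: str = "consensus", n_reps: int = 150,
            tau: float = 0.5, gamma: float = 1.0, n_null: int = 0,
            q_level: float = 0.05, cv_schemes: tuple[str, ...] = ("loo",),
            cv_repeats: int = 10, n_perm: int = 0,
            classify_groups: tuple[str, str] = ("TB", "PB-TEA")) -> StudyResults:
        """Run the full analysis and return a results object.

        ``partition`` is ``"consensus"`` (150-rep agreement-matrix consensus,
        the study's procedure) or ``"louvain"`` (one seeded run per subject,
        cheaper). ``n_null`` > 0 adds rewired-null small-worldness to the
        global metrics. ``n_perm`` > 0 adds the label-shuffling chance band
        to the first CV scheme's report.
        """
        rng = np.random.default_rng(seed)
        prepared = self._prepared()
        meta = self.meta

        # --- per-subject metrics ------------------------------------------------
        rows = []
        nodal = {m: {} for m in NODAL_METRICS}
        partitions, hub_classes = {}, {}
        hemi_rows = []
        for c in self.connectomes:
            sid = c.subject_id
            W = prepared[sid]
            ci, cbar = metrics.weighted_clustering(W)
            _, lbar = metrics.shortest_path_lengths(W)
            part_seed = int(rng.integers(2**31 - 1))
            if partition == "consensus":
                part = comm.consensus_partition(W, n_reps=n_reps, tau=tau,
                                                gamma=gamma, seed=part_seed)
            else:
                part = comm.louvain(W, gamma=gamma, seed=part_seed)
            z = comm.within_module_degree(W, part.assignment)
            p = comm.participation_coefficient(W, part.assignment)
            hubs = comm.classify_hubs(z, p)
            row = {
                "subject_id": sid, "group": meta.loc[sid, "group"],
                "clustering": cbar, "path_length": lbar, "modularity": part.q,
                "density": construct.connective_density(W),
            }
            if n_null > 0:
                s, _, _ = metrics.small_worldness(W, n_null=n_null,
                                                  seed=int(rng.integers(2**31 - 1)))
                row["small_worldness"] = s
            rows.append(row)
            nodal["clustering"][sid] = ci
            nodal["within_module_degree"][sid] = z
            nodal["participation"][sid] = p
            partitions[sid] = part.assignment
            hub_classes[sid] = hubs
            # hemispheric metrics on the masked subnetworks
            left, right = construct.hemisphere_subnetworks(
                c.copy_with(W, subject_id=sid))
            for side, sub in (("L", left), ("R", right)):
                _, c_h = metrics.weighted_clustering(sub.weights)
                _, l_h = metrics.shortest_path_lengths(sub.weights)
                q_h = comm.louvain(sub.weights, gamma=gamma,
                                   seed=int(rng.integers(2**31 - 1))).q
                hemi_rows.append({"subject_id": sid, "group": meta.loc[sid, "group"],
                                  "side": side, "clustering": c_h,
                                  "path_length": l_h, "modularity": q_h})

        global_table = pd.DataFrame(rows).set_index("subject_id", drop=False)
        hemi_table = pd.DataFrame(hemi_rows)
        nodal_frames = {m: pd.DataFrame(nodal[m]).T for m in NODAL_METRICS}
        hub_counts = pd.DataFrame(
            [{"subject_id": sid, "group": meta.loc[sid, "group"],
              "n_provincial": comm.count_hubs(h)[0],
              "n_connector": comm.count_hubs(h)[1]}
             for sid, h in hub_classes.items()]).set_index("subject_id", drop=False)
        prevalence = comm.hub_prevalence(
            [hub_classes[sid] for sid in meta.subject_id],
            meta.group.tolist())

        # --- group comparisons --------------------------------------------------
        pairs = self._pairs()
        # density is reported descriptively (group means) but, as in the
        # study design, only the topology metrics are tested for group
        # differences
        glob_metrics = [m for m in global_table.columns
                        if m in ("clustering", "path_length", "modularity",
                                 "small_worldness")]
        cls_sel_ids = meta[meta.group.isin(["PB-TEA", "TB"])].subject_id
        cov = self._covariate_matrix(cls_sel_ids)

        def paired_series(tbl: pd.DataFrame, col: str) -> st.StatResult:
            return st.paired_t(tbl.loc[pairs.ab, col].to_numpy(),
                               tbl.loc[pairs.tea, col].to_numpy())

        def ancova_series(tbl: pd.DataFrame, col: str) -> st.StatResult:
            return st.ancova_group_effect(tbl.loc[cls_sel_ids, col].to_numpy(),
                                          meta.loc[cls_sel_ids, "group"].to_numpy(),
                                          cov)

        def corrected(rows: list[dict]) -> pd.DataFrame:
            df = pd.DataFrame(rows)
            rej, q = st.fdr_bh(df.p.to_numpy(), q_level=q_level)
            df["q"], df["significant"] = q, rej
            return df

        grows = []
        for m in glob_metrics:
            grows.append(_result_row(paired_series(global_table, m),
                                     contrast="PB-AB vs PB-TEA", metric=m, test="paired_t"))
            grows.append(_result_row(ancova_series(global_table, m),
                                     contrast="PB-TEA vs TB", metric=m, test="ancova"))
        gdf = pd.DataFrame(grows)
        out = []
        for contrast, sub in gdf.groupby("contrast"):
            rej, q = st.fdr_bh(sub.p.to_numpy(), q_level=q_level)
            sub = sub.assign(q=q, significant=rej)
            out.append(sub)
        global_comparisons = pd.concat(out, ignore_index=True)

        nrows = []
        for m in NODAL_METRICS:
            tbl = nodal_frames[m]
            fam = [_result_row(paired_series(tbl, node),
                               contrast="PB-AB vs PB-TEA", metric=m, node=node,
                               test="paired_t")
                   for node in tbl.columns]
            nrows.append(corrected(fam))
            fam = [_result_row(ancova_series(tbl, node),
                               contrast="PB-TEA vs TB", metric=m, node=node,
                               test="ancova")
                   for node in tbl.columns]
            nrows.append(corrected(fam))
        nodal_comparisons = pd.concat(nrows, ignore_index=True)

        hrows = []
        for col in ("n_provincial", "n_connector"):
            hrows.append(_result_row(paired_series(hub_counts, col),
                                     contrast="PB-AB vs PB-TEA", metric=col,
                                     test="paired_t"))
            hrows.append(_result_row(ancova_series(hub_counts.astype({col: float}), col),
                                     contrast="PB-TEA vs TB", metric=col, test="ancova"))
        hub_count_comparisons = corrected(hrows)

        # --- hemispheric asymmetry ---------------------------------------------
        arows = []
        for grp, sub in hemi_table.groupby("group"):
            wide = sub.pivot(index="subject_id", columns="side",
                             values=["clustering", "path_length", "modularity"])
            left = {m: wide[(m, "L")].to_numpy() for m in ("clustering", "path_length", "modularity")}
            right = {m: wide[(m, "R")].to_numpy() for m in ("clustering", "path_length", "modularity")}
            res = st.hemispheric_asymmetry(left, right, q_level=q_level)
            for m, r in res.items():
                arows.append(_result_row(r, group=grp, metric=m))
        asymmetry = pd.DataFrame(arows)

        # --- FA partial correlations -------------------------------------------
        fa_rows = []
        cohorts = {"PB-AB + PB-TEA": ["PB-AB", "PB-TEA"], "PB-TEA + TB": ["PB-TEA", "TB"]}
        for name, groups in cohorts.items():
            sel = meta[meta.group.isin(groups)].subject_id
            covm = self._covariate_matrix(sel)
            fa = meta.loc[sel, "mean_fa"].to_numpy()
            for m in ("clustering", "path_length"):
                r, p = st.partial_correlation(global_table.loc[sel, m].to_numpy(), fa, covm)
                fa_rows.append({"cohort": name, "metric": m, "r": r, "p": p})
        fa_correlations = pd.DataFrame(fa_rows)

        # --- classification -----------------------------------------------------
        classification: dict[str, clf.ClassifierReport] = {}
        feature_projection = None
        cls_sel = meta[meta.group.isin(classify_groups)].subject_id.tolist()
        if len(cls_sel) >= 6:
            fm = clf.assemble_features({
                sid: {m: nodal_frames[m].loc[sid].to_numpy() for m in NODAL_METRICS}
                for sid in cls_sel})
            labels = meta.loc[cls_sel, "group"].to_numpy()
            for i, scheme in enumerate(cv_schemes):
                rep = clf.cross_validate(
                    fm.values, labels, scheme=scheme,
                    n_repeats=1 if scheme.lower() in ("loo", "leaveoneout") else cv_repeats,
                    seed=int(rng.integers(2**31 - 1)), positive_label="PB-TEA")
                if i == 0 and n_perm > 0:
                    rep = clf.permutation_test(fm.values, labels, scheme=scheme,
                                               n_perm=n_perm,
                                               seed=int(rng.integers(2**31 - 1)),
                                               report=rep)
                classification[rep.scheme] = rep
            feature_projection = clf.per_feature_projection(fm)
            feature_projection["group"] = labels

        return StudyResults(
            node_labels=list(self.connectomes[0].node_labels),
            global_table=global_table, nodal=nodal_frames, partitions=partitions,
            hub_classes=hub_classes, hub_counts=hub_counts, hub_prevalence=prevalence,
            global_comparisons=global_comparisons, nodal_comparisons=nodal_comparisons,
            hub_count_comparisons=hub_count_comparisons, asymmetry=asymmetry,
            fa_correlations=fa_correlations, classification=classification,
            feature_projection=feature_projection,
        )
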