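"""Synthetic neonatal connectome cohorts with planted structure.

The generator emulates the study design the pipeline targets: 28 preterm
infants scanned twice (at birth, PB-AB, and at term-equivalent age, PB-TEA)
plus 28 matched term-born controls (TB). Each subject's 90-node weighted
matrix is drawn from a planted modular (stochastic-block-like) model:
within-module edges have mean weight ``w_in``, between-module edges
``w_out``, with truncated-Gaussian edge noise and a per-infant lognormal
scale factor shared by an infant's two scans. Group effects are
multiplicative: PB-AB networks get stronger within-module and weaker
between-module weights than PB-TEA (so planted clustering and modularity
decrease from birth to term-equivalent age), while PB-TEA differs from TB
only on a designated set of "affected" regions (insula, cingulate and
subcortical labels), whose mutual edges are boosted — a purely nodal
effect. A mean-FA surrogate is drawn as a decreasing linear function of the
subject's mean clustering, giving the negative metric–FA coupling the
statistics layer should recover.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .connectome import Connectome, write_matrix

__all__ = [
    "GroupEffect",
    "FACoupling",
    "CohortSpec",
    "SubjectRecord",
    "DEFAULT_AFFECTED_LABELS",
    "region_table",
    "generate_planted_connectome",
    "generate_edge_lengths",
    "generate_cohort",
    "write_cohort",
    "read_cohort",
]

# 45 bilateral region abbreviations in an AAL-like ordering (interleaved L/R)
_REGIONS = [
    "PreCG", "SFGdor", "ORBsup", "MFG", "ORBmid", "IFGoperc", "IFGtriang",
    "ORBinf", "ROL", "SMA", "OLF", "SFGmed", "ORBsupmed", "REC", "INS",
    "ACG", "DCG", "HIP", "AMYG", "THA", "PCG", "PHG", "CUN", "LING", "SOG",
    "MOG", "IOG", "FFG", "PoCG", "SPG", "IPL", "SMG", "ANG", "PCUN", "PCL",
    "CAU", "PUT", "PAL", "CAL", "HES", "STG", "TPOsup", "MTG", "TPOmid", "ITG",
]

# limbic / subcortical regions carrying the planted nodal (PB-TEA vs TB) effect
DEFAULT_AFFECTED_LABELS = [
    f"{r}.{h}" for r in ("INS", "ACG", "DCG", "HIP", "AMYG", "THA") for h in ("L", "R")
]

GROUPS = ("PB-AB", "PB-TEA", "TB")


def region_table(n_nodes: int = 90) -> pd.DataFrame:
    """Region labels and hemispheres, interleaved L/R as in the AAL-90 ordering."""
    labels, hemis = [], []
    for i in range(n_nodes):
        base = _REGIONS[(i // 2) % len(_REGIONS)]
        suffix = "" if (i // 2) < len(_REGIONS) else f"{i // 2}"
        h = "L" if i % 2 == 0 else "R"
        labels.append(f"{base}{suffix}.{h}")
        hemis.append(h)
    return pd.DataFrame({"label": labels, "hemisphere": hemis})


@dataclass
class GroupEffect:
    """Multiplicative shifts applied to one group's planted connectivity.

    ``w_in_mult`` / ``w_out_mult`` scale the conditional weight of
    within- / between-module connections; ``p_out_mult`` scales the
    *presence probability* of between-module connections (fewer long
    between-module connections means sparser, more segregated networks —
    higher clustering and modularity); ``affected_mult`` uniformly scales
    the weights of edges among the designated affected node set;
    with ``affected_rebalance`` (default) the expected weight removed from
    the affected set's mutual connections is spread over the remaining
    within-module connections of the network (a fraction-of-a-percent
    boost per edge), keeping the total intra-modular weight — and hence
    modularity and the fractional-scaling denominator — essentially
    unchanged, so the planted alteration stays nodal: lower clustering and
    higher participation at the affected nodes only.
    """

    w_in_mult: float = 1.0
    w_out_mult: float = 1.0
    p_in_mult: float = 1.0
    p_out_mult: float = 1.0
    noise_mult: float = 1.0
    affected_mult: float = 1.0
    affected_rebalance: float = 1.0   # fraction of the removed weight spread back


@dataclass
class FACoupling:
    """Linear surrogate for whole-brain mean fractional anisotropy.

    mean_fa = intercept - slope * (subject mean clustering) + N(0, noise_sd),
    clipped into (0, 1). A positive slope yields the negative
    clustering–FA association.
    """

    intercept: float = 0.35
    slope: float = 0.50
    noise_sd: float = 0.015


def _default_group_effects() -> dict[str, GroupEffect]:
    return {
        # stronger segregation at preterm birth: far fewer between-module
        # connections, so clustering and modularity DECREASE from PB-AB to
        # PB-TEA while density increases
        "PB-AB": GroupEffect(p_out_mult=0.40),
        "PB-TEA": GroupEffect(),
        # nodal-only difference: the TB limbic/subcortical community is
        # less tightly intra-connected, so clustering there is higher and
        # participation lower in PB-TEA than TB. The remaining multipliers
        # are small compensators, solved numerically once, that cancel the
        # global side effects of the nodal planting so the two groups'
        # mean clustering, path length, modularity and density coincide
        # (the planted contrast is purely nodal).
        # nodal planting plus small compensators (solved numerically once)
        # that cancel its global side effects, so the TEA/TB contrast is
        # purely nodal
        "TB": GroupEffect(affected_mult=0.70, w_out_mult=1.0091, p_in_mult=1.0005,
                          p_out_mult=0.9769, noise_mult=1.0057),
    }


@dataclass
class CohortSpec:
    """Full description of a synthetic cohort; same spec + seed -> identical cohort."""

    n_pairs: int = 28
    n_controls: int = 28
    n_nodes: int = 90
    module_sizes: list[int] | None = None
    w_in: float = 10.0            # conditional mean weight of within-module connections
    w_in_affected: float = 5.0    # within-module weight of the affected (limbic) community
    w_out: float = 3.0            # conditional mean weight of between-module connections
    p_in: float = 0.85            # presence probability of within-module connections
    p_out: float = 0.20           # presence probability of between-module connections
    group_effects: dict[str, GroupEffect] = field(default_factory=_default_group_effects)
    affected_labels: list[str] = field(default_factory=lambda: list(DEFAULT_AFFECTED_LABELS))
    noise_sd: float = 1.0
    subject_sd: float = 0.15      # sigma of the per-infant segregation random effect
    fa_coupling: FACoupling = field(default_factory=FACoupling)
    confound: bool = False        # couple covariates to group and to the network scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.module_sizes is None:
            if self.n_nodes == 90:
                # the limbic/subcortical community (the 12 affected labels,
                # nodes 28..39) forms its own planted module
                self.module_sizes = [28, 12, 25, 25]
            else:
                base = self.n_nodes // 4
                rem = self.n_nodes - 4 * base
                self.module_sizes = [base + (1 if i < rem else 0) for i in range(4)]
        if sum(self.module_sizes) != self.n_nodes:
            raise ValueError(
                f"module_sizes sum to {sum(self.module_sizes)}, expected n_nodes={self.n_nodes}"
            )
        if self.w_in <= 0 or self.w_out < 0:
            raise ValueError("weight parameters must be positive")
        if self.n_pairs < 2 or self.n_controls < 2:
            raise ValueError("need at least 2 pairs and 2 controls")
        for g in GROUPS:
            if g not in self.group_effects:
                self.group_effects[g] = GroupEffect()

    def null(self) -> "CohortSpec":
        """Copy with every planted effect removed (group shifts and the
        FA–clustering coupling), for type-I-error calibration."""
        return replace(
            self,
            group_effects={g: GroupEffect() for g in GROUPS},
            fa_coupling=replace(self.fa_coupling, slope=0.0),
        )

    def module_assignment(self) -> np.ndarray:
        return np.repeat(np.arange(len(self.module_sizes)), self.module_sizes)

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "CohortSpec":
        d = json.loads(text)
        d["group_effects"] = {g: GroupEffect(**e) for g, e in d["group_effects"].items()}
        d["fa_coupling"] = FACoupling(**d["fa_coupling"])
        return cls(**d)


@dataclass
class SubjectRecord:
    """Metadata for one scan."""

    subject_id: str
    group: str                 # PB-AB | PB-TEA | TB
    pair_id: str               # links an infant's two scans and the TEA<->TB match
    pma_scan: float            # postmenstrual age at scan, weeks
    head_circumference: float  # cm
    n_embryos: int             # 1 singleton, 2 twin
    sex: str                   # M | F
    motion: float              # absolute head motion, arbitrary units
    mean_fa: float             # whole-brain mean FA surrogate, in (0, 1)

    def __post_init__(self) -> None:
        if not 0 < self.mean_fa < 1:
            raise ValueError("mean_fa must lie in (0, 1)")
        if self.pma_scan <= 0:
            raise ValueError("pma_scan must be positive")
        if self.group not in GROUPS:
            raise ValueError(f"unknown group {self.group!r}")


def _draw_weights(P: np.ndarray, M: np.ndarray, noise_sd: float,
                  rng: np.random.Generator) -> np.ndarray:
    """Sparse planted weights: a connection exists with probability P_ij
    and, when present, carries weight N(M_ij, noise_sd) truncated at zero
    (weights are counts-like and cannot be negative)."""
    n = P.shape[0]
    present = rng.random((n, n)) < P
    W = np.where(present, M, 0.0)
    if noise_sd > 0:
        W = W + np.where(W > 0, rng.normal(0.0, noise_sd, (n, n)), 0.0)
    W = np.triu(np.maximum(W, 0.0), k=1)
    W = W + W.T
    return W


def _planted_weights(n_nodes: int, module_sizes: list[int], w_in: float, w_out: float,
                     noise_sd: float, rng: np.random.Generator,
                     p_in: float = 1.0, p_out: float = 1.0) -> np.ndarray:
    m = np.repeat(np.arange(len(module_sizes)), module_sizes)
    same = m[:, None] == m[None, :]
    P = np.where(same, p_in, p_out)
    M = np.where(same, w_in, w_out).astype(float)
    return _draw_weights(P, M, noise_sd, rng)


def generate_planted_connectome(n_nodes: int, module_sizes: list[int], w_in: float,
                                w_out: float, noise_sd: float = 0.0,
                                seed: int | None = None, p_in: float = 1.0,
                                p_out: float = 1.0) -> Connectome:
    """Single connectome from the planted modular model (no group effects).

    With the default full presence probabilities the expected within- and
    between-block weights equal ``w_in`` and ``w_out`` exactly.
    """
    if sum(module_sizes) != n_nodes:
        raise ValueError(f"module_sizes sum to {sum(module_sizes)}, expected {n_nodes}")
    rng = np.random.default_rng(seed)
    W = _planted_weights(n_nodes, module_sizes, w_in, w_out, noise_sd, rng,
                         p_in=p_in, p_out=p_out)
    nodes = region_table(n_nodes)
    return Connectome(weights=W, node_labels=nodes["label"].tolist(),
                      node_hemisphere=nodes["hemisphere"].tolist(),
                      subject_id=f"planted-{seed}")


def generate_edge_lengths(n_nodes: int, seed: int | None = None,
                          box_mm: tuple[float, float, float] = (120.0, 150.0, 100.0)
                          ) -> tuple[np.ndarray, pd.DataFrame]:
    """Euclidean inter-node distances from random 3D coordinates.

    Nodes are placed uniformly in a head-sized box; hemisphere follows the
    sign of x, with the left/right counts forced equal (balanced split at
    the midline). Returns (lengths, node table with label/hemisphere/x/y/z).
    """
    if n_nodes < 2:
        raise ValueError("need at least 2 nodes")
    rng = np.random.default_rng(seed)
    nodes = region_table(n_nodes)
    half_x = box_mm[0] / 2
    x = np.where(
        np.asarray(nodes["hemisphere"]) == "L",
        rng.uniform(-half_x, 0.0, n_nodes),
        rng.uniform(0.0, half_x, n_nodes),
    )
    y = rng.uniform(0.0, box_mm[1], n_nodes)
    z = rng.uniform(0.0, box_mm[2], n_nodes)
    coords = np.column_stack([x, y, z])
    diff = coords[:, None, :] - coords[None, :, :]
    lengths = np.sqrt((diff**2).sum(axis=-1))
    nodes = nodes.assign(x=x, y=y, z=z)
    return lengths, nodes


def _subject_weights(spec: CohortSpec, group: str, segregation: float, scale: float,
                     rng: np.random.Generator, affected_idx: np.ndarray) -> np.ndarray:
    """One scan's weights.

    ``segregation`` is the infant's random effect u (shared by a preterm
    infant's two scans): the between-module presence probability is scaled
    by exp(-u), so more segregated individuals have sparser between-module
    connectivity. ``scale`` is an overall lognormal factor emulating
    per-subject streamline yield; fractional scaling removes it downstream.
    """
    eff = spec.group_effects[group]
    p_out = float(np.clip(spec.p_out * eff.p_out_mult * np.exp(-segregation), 0.0, 1.0))
    p_in = float(np.clip(spec.p_in * eff.p_in_mult, 0.0, 1.0))
    m = spec.module_assignment()
    same = m[:, None] == m[None, :]
    P = np.where(same, p_in, p_out)
    M = np.where(same, spec.w_in * eff.w_in_mult, spec.w_out * eff.w_out_mult).astype(float)
    mask = np.zeros(spec.n_nodes, dtype=bool)
    mask[affected_idx] = True
    both = mask[:, None] & mask[None, :]
    # the limbic/subcortical community is more weakly self-connected than
    # the cortical modules in every group
    M = np.where(same & both, spec.w_in_affected * eff.w_in_mult, M)
    if affected_idx.size and eff.affected_mult != 1.0:
        target = same & both
        removed_exp = float((P * M)[target].sum()) * (1.0 - eff.affected_mult)
        M = np.where(target, M * eff.affected_mult, M)
        if eff.affected_rebalance != 0.0 and removed_exp != 0.0:
            other = same & ~target
            np.fill_diagonal(other, False)
            other_exp = float((P * M)[other].sum())
            if other_exp > 0:
                M = np.where(other, M * (1.0 + eff.affected_rebalance * removed_exp / other_exp), M)
    W = _draw_weights(P, M, spec.noise_sd * eff.noise_mult, rng)
    return W * scale


def _mean_clustering(W: np.ndarray) -> float:
    # local import avoids a cycle (metrics does not depend on simulate)
    from .construct import fractional_scale
    from .metrics import weighted_clustering

    _, c = weighted_clustering(fractional_scale(W))
    return c


def generate_cohort(spec: CohortSpec) -> tuple[list[Connectome], list[SubjectRecord]]:
    """Draw the full three-group cohort.

    Returns 2*n_pairs + n_controls connectomes and aligned metadata
    records. Each preterm infant's two scans share a pair_id and a random
    scale factor; the i-th control shares the i-th pair's pair_id (the
    TEA<->TB matching). All edge lengths come from one cohort-level node
    layout, mimicking population-template registration.
    """
    root = np.random.SeedSequence(spec.seed)
    layout_seq, cov_seq, *subj_seqs = root.spawn(2 + spec.n_pairs + spec.n_controls)
    lengths, nodes = generate_edge_lengths(spec.n_nodes,
                                           seed=int(layout_seq.generate_state(1)[0] % 2**31))
    labels = nodes["label"].tolist()
    hemis = nodes["hemisphere"].tolist()
    affected_idx = np.flatnonzero(pd.Index(labels).isin(spec.affected_labels))
    cov_rng = np.random.default_rng(cov_seq)

    connectomes: list[Connectome] = []
    records: list[SubjectRecord] = []

    def make_record(sid: str, group: str, pair: str, pma: float, hc: float,
                    emb: int, sex: str, motion: float, W: np.ndarray) -> None:
        fa_c = spec.fa_coupling
        fa = (fa_c.intercept - fa_c.slope * _mean_clustering(W)
              + cov_rng.normal(0.0, fa_c.noise_sd))
        fa = float(np.clip(fa, 1e-3, 1 - 1e-3))
        records.append(SubjectRecord(
            subject_id=sid, group=group, pair_id=pair, pma_scan=pma,
            head_circumference=hc, n_embryos=emb, sex=sex, motion=motion, mean_fa=fa,
        ))
        connectomes.append(Connectome(weights=W, lengths=lengths.copy(),
                                      node_labels=labels, node_hemisphere=hemis,
                                      subject_id=sid))

    for p in range(spec.n_pairs):
        pair = f"pair{p:02d}"
        rng = np.random.default_rng(subj_seqs[p])
        seg = float(rng.normal(0.0, spec.subject_sd))
        scale = float(np.exp(rng.normal(0.0, spec.subject_sd)))
        sex = "M" if cov_rng.random() < 0.5 else "F"
        emb = 2 if cov_rng.random() < 0.25 else 1
        pma_ab = float(cov_rng.uniform(29.0, 37.0))
        pma_tea = float(cov_rng.uniform(38.0, 43.0) if spec.confound
                        else cov_rng.uniform(38.0, 45.0))
        hc_ab = float(cov_rng.normal(28.0, 1.5))
        hc_tea = float(cov_rng.normal(33.5, 1.2))
        mot_ab = float(abs(cov_rng.normal(0.5, 0.15)))
        mot_tea = float(abs(cov_rng.normal(0.7, 0.20)))
        W_ab = _subject_weights(spec, "PB-AB", seg, scale, rng, affected_idx)
        W_tea = _subject_weights(spec, "PB-TEA", seg, scale, rng, affected_idx)
        if spec.confound:
            W_tea = W_tea * (1.0 + 0.05 * (pma_tea - 40.0))
        make_record(f"sub-PB{p:02d}-AB", "PB-AB", pair, pma_ab, hc_ab, emb, sex, mot_ab, W_ab)
        make_record(f"sub-PB{p:02d}-TEA", "PB-TEA", pair, pma_tea, hc_tea, emb, sex, mot_tea, W_tea)

    for c in range(spec.n_controls):
        pair = f"pair{c:02d}" if c < spec.n_pairs else f"ctrl{c:02d}"
        rng = np.random.default_rng(subj_seqs[spec.n_pairs + c])
        seg = float(rng.normal(0.0, spec.subject_sd))
        scale = float(np.exp(rng.normal(0.0, spec.subject_sd)))
        sex = "M" if cov_rng.random() < 0.5 else "F"
        emb = 2 if cov_rng.random() < 0.25 else 1
        pma = float(cov_rng.uniform(40.0, 45.0) if spec.confound
                    else cov_rng.uniform(38.0, 45.0))
        hc = float(cov_rng.normal(34.0, 1.2))
        mot = float(abs(cov_rng.normal(0.7, 0.20)))
        W = _subject_weights(spec, "TB", seg, scale, rng, affected_idx)
        if spec.confound:
            W = W * (1.0 + 0.05 * (pma - 40.0))
        make_record(f"sub-TB{c:02d}", "TB", pair, pma, hc, emb, sex, mot, W)

    return connectomes, records


def write_cohort(path: str | Path, connectomes: list[Connectome],
                 records: list[SubjectRecord], spec: CohortSpec | None = None) -> None:
    """Write one TSV matrix per subject, the shared lengths TSV, the
    metadata CSV, and (optionally) the generating spec as a JSON sidecar."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    for c in connectomes:
        write_matrix(path / f"{c.subject_id}.tsv", c.weights)
    if connectomes and connectomes[0].lengths is not None:
        write_matrix(path / "lengths.tsv", connectomes[0].lengths)
    first = connectomes[0]
    region_df = pd.DataFrame({"label": first.node_labels,
                              "hemisphere": first.node_hemisphere})
    region_df.to_csv(path / "nodes.csv", index=False)
    pd.DataFrame([asdict(r) for r in records]).to_csv(path / "cohort.csv", index=False)
    if spec is not None:
        (path / "cohort_spec.json").write_text(spec.to_json())


def read_cohort(path: str | Path) -> tuple[list[Connectome], list[SubjectRecord]]:
    """Inverse of :func:`write_cohort`."""
    from .connectome import read_connectome

    path = Path(path)
    meta = pd.read_csv(path / "cohort.csv")
    lengths_path = path / "lengths.tsv"
    connectomes, records = [], []
    for _, row in meta.iterrows():
        rec = SubjectRecord(**{k: row[k] for k in (
            "subject_id", "group", "pair_id", "pma_scan", "head_circumference",
            "n_embryos", "sex", "motion", "mean_fa")})
        c = read_connectome(path / f"{rec.subject_id}.tsv", nodes_path=path / "nodes.csv",
                            lengths_path=lengths_path if lengths_path.exists() else None,
                            subject_id=rec.subject_id)
        connectomes.append(c)
        records.append(rec)
    return connectomes, records
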