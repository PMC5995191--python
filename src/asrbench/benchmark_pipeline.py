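"""Orchestration of the full simulation study.

A scenario grid (taxon count x sampling fraction x tree height x indel rate)
is expanded into seeded replicates: for each tree replicate a birth-death
tree is simulated, for each sequence replicate sequences evolve down it, and
each aligner adapter produces a tip MSA from which ancestors are
reconstructed on the TRUE tree with the TRUE model parameters and scored
against the true ancestral sequences.  The long-format benchmark table then
feeds the statistical comparisons: pairwise Mann-Whitney tests with
Benjamini-Hochberg correction, accuracy-by-depth profiles, indel bias
summaries, and correlations between MSA quality and reconstruction accuracy.

Seeding is hierarchical and documented: the master seed and a CRC-32 hash of
the scenario id form a numpy SeedSequence, whose spawned children seed the
(tree replicate, sequence replicate) streams.  Identical configuration and
master seed reproduce the study byte for byte.
"""

from __future__ import annotations

import itertools
import os
import subprocess
import tempfile
import zlib
from dataclasses import dataclass
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.cluster.hierarchy import linkage
from scipy.spatial.distance import pdist
from statsmodels.stats.multitest import multipletests

from .accuracy_metrics import (
    PairwiseAlignmentParams,
    _affine_dp,
    _scoring_matrix,
    reconstruction_accuracy,
    score_msa,
)
from .asr_engine import reconstruct
from .errors import AdapterError, ConfigurationError
from .phylo_sim import Phylogeny, TreeSimParams, node_depths, simulate_tree, write_newick
from .protein_sim import (
    GAP,
    EvolutionHistory,
    IndelParams,
    RateModel,
    evolve,
    tip_fasta,
)

__all__ = [
    "ScenarioSpec",
    "GridConfig",
    "AlignerAdapter",
    "scenario_grid",
    "default_grid",
    "run_scenario",
    "compare_aligners",
    "depth_profile",
    "indel_bias",
    "quality_vs_accuracy",
    "builtin_progressive_align",
    "baseline_adapter",
    "builtin_adapter",
    "external_adapter",
]

QUALITY_METRICS = ["sp_score", "modeler_score", "tc_score", "cline_shift"]


# -- scenario grid ---------------------------------------------------------


@dataclass(frozen=True)
class ScenarioSpec:
    """One cell of the simulation grid plus its replication settings."""

    n_taxa: int
    sampling_fraction: float
    height: float
    indel_rate: float
    birth_rate: float = 6.0
    death_rate: float = 3.0
    root_length: int = 408
    gamma_shape: float = 1.8
    n_categories: int = 4
    zipf_exponent: float = 1.7
    max_indel_length: int = 20
    n_tree_reps: int = 10
    n_seq_reps: int = 10

    @property
    def scenario_id(self) -> str:
        return (
            f"taxa{self.n_taxa}_rho{self.sampling_fraction}_h{self.height}"
            f"_indel{self.indel_rate}"
        )

    def rate_model(self) -> RateModel:
        return RateModel(gamma_shape=self.gamma_shape, n_categories=self.n_categories)

    def indel_params(self) -> IndelParams:
        return IndelParams(
            insertion_rate=self.indel_rate,
            deletion_rate=self.indel_rate,
            zipf_exponent=self.zipf_exponent,
            max_length=self.max_indel_length,
        )


@dataclass(frozen=True)
class GridConfig:
    """Candidate values per grid axis; the study defaults follow the
    benchmark's design (3 taxon counts x 3 sampling fractions x 4 heights x
    2 indel rates = 72 scenarios; 10 trees x 10 sequence sets each)."""

    taxa: Sequence[int] = (16, 32, 64)
    sampling_fractions: Sequence[float] = (0.01, 0.25, 0.99)
    heights: Sequence[float] = (0.8, 1.0, 1.2, 2.0)
    indel_rates: Sequence[float] = (0.01, 0.05)
    n_tree_reps: int = 10
    n_seq_reps: int = 10
    root_length: int = 408
    gamma_shape: float = 1.8
    n_categories: int = 4
    zipf_exponent: float = 1.7
    max_indel_length: int = 20
    birth_rate: float = 6.0
    death_rate: float = 3.0


def scenario_grid(config: GridConfig = GridConfig()) -> List[ScenarioSpec]:
    """Cartesian product of the grid axes in deterministic order."""
    for name in ("taxa", "sampling_fractions", "heights", "indel_rates"):
        if not getattr(config, name):
            raise ConfigurationError(f"empty candidate list for {name}")
    grid = []
    for n, rho, h, r in itertools.product(
        config.taxa, config.sampling_fractions, config.heights, config.indel_rates
    ):
        grid.append(
            ScenarioSpec(
                n_taxa=n,
                sampling_fraction=rho,
                height=h,
                indel_rate=r,
                birth_rate=config.birth_rate,
                death_rate=config.death_rate,
                root_length=config.root_length,
                gamma_shape=config.gamma_shape,
                n_categories=config.n_categories,
                zipf_exponent=config.zipf_exponent,
                max_indel_length=config.max_indel_length,
                n_tree_reps=config.n_tree_reps,
                n_seq_reps=config.n_seq_reps,
            )
        )
    return grid


def default_grid() -> List[ScenarioSpec]:
    """The full 72-scenario study grid."""
    return scenario_grid(GridConfig())


def scenario_seed_sequence(master_seed: int, scenario_id: str) -> np.random.SeedSequence:
    """Stable seed derivation: master seed plus CRC-32 of the scenario id."""
    return np.random.SeedSequence([int(master_seed), zlib.crc32(scenario_id.encode())])


# -- aligner adapters ------------------------------------------------------


@dataclass(frozen=True)
class AlignerAdapter:
    """How to obtain a tip MSA for one replicate.

    ``mode`` is one of 'true_alignment_baseline', 'builtin_progressive' or
    'external_command'.  External commands are templates with ``{in}``,
    ``{out}`` and (when ``guide_tree`` is set) ``{tree}`` placeholders; a
    trailing '*' in the identifier conventionally marks guide-tree use.
    Output must contain exactly the input sequences once degapped.
    """

    identifier: str
    mode: str
    command: str = ""
    guide_tree: bool = False

    def align(self, history: EvolutionHistory) -> Dict[str, str]:
        tips = history.tree.tip_labels
        if self.mode == "true_alignment_baseline":
            msa = {t: history.true_alignment[t] for t in tips}
            return _drop_allgap_columns(msa)
        if self.mode == "builtin_progressive":
            return builtin_progressive_align({t: history.sequences[t] for t in tips})
        if self.mode == "external_command":
            return self._run_external(history)
        raise ConfigurationError(f"unknown adapter mode {self.mode!r}")

    def _run_external(self, history: EvolutionHistory) -> Dict[str, str]:
        from .asr_engine import read_fasta_alignment

        tips = history.tree.tip_labels
        with tempfile.TemporaryDirectory() as tmp:
            fin = os.path.join(tmp, "in.fasta")
            fout = os.path.join(tmp, "out.fasta")
            ftree = os.path.join(tmp, "guide.nwk")
            with open(fin, "w") as fh:
                fh.write(tip_fasta(history))
            subs = {"in": fin, "out": fout}
            if self.guide_tree:
                with open(ftree, "w") as fh:
                    fh.write(write_newick(history.tree) + "\n")
                subs["tree"] = ftree
            cmd = self.command.format(**subs)
            use_stdout = "{out}" not in self.command
            try:
                if use_stdout:
                    with open(fout, "w") as out_fh:
                        subprocess.run(cmd, shell=True, stdout=out_fh,
                                       stderr=subprocess.DEVNULL, check=True)
                else:
                    subprocess.run(cmd, shell=True, stdout=subprocess.DEVNULL,
                                   stderr=subprocess.DEVNULL, check=True)
            except subprocess.CalledProcessError as exc:
                raise AdapterError(f"{self.identifier}: command failed: {exc}") from exc
            if not os.path.exists(fout) or os.path.getsize(fout) == 0:
                raise AdapterError(f"{self.identifier}: no output produced")
            with open(fout) as fh:
                msa = read_fasta_alignment(fh.read())
        check_degapped_identity(msa, {t: history.sequences[t] for t in tips}, self.identifier)
        return msa


def check_degapped_identity(msa: Mapping[str, str], seqs: Mapping[str, str], who: str) -> None:
    if set(msa) != set(seqs):
        raise AdapterError(f"{who}: output labels differ from input labels")
    for k, s in seqs.items():
        if msa[k].replace(GAP, "") != s:
            raise AdapterError(f"{who}: degapped output differs from input for {k!r}")


def baseline_adapter() -> AlignerAdapter:
    return AlignerAdapter("baseline", "true_alignment_baseline")


def builtin_adapter() -> AlignerAdapter:
    return AlignerAdapter("builtin", "builtin_progressive")


def external_adapter(identifier: str, command: str, guide_tree: bool = False) -> AlignerAdapter:
    return AlignerAdapter(identifier, "external_command", command, guide_tree)


def _drop_allgap_columns(msa: Mapping[str, str]) -> Dict[str, str]:
    labels = list(msa)
    keep = [
        c for c in range(len(next(iter(msa.values()))))
        if any(msa[k][c] != GAP for k in labels)
    ]
    return {k: "".join(msa[k][c] for c in keep) for k in labels}


# -- builtin progressive aligner ------------------------------------------


def _kmer_profile_distances(seqs: List[str], k: int = 3) -> np.ndarray:
    k = min(k, max(1, min(len(s) for s in seqs)))
    vocab: Dict[str, int] = {}
    rows = []
    for s in seqs:
        counts: Dict[int, int] = {}
        for i in range(len(s) - k + 1):
            key = vocab.setdefault(s[i:i + k], len(vocab))
            counts[key] = counts.get(key, 0) + 1
        rows.append(counts)
    mat = np.zeros((len(seqs), len(vocab) or 1))
    for i, counts in enumerate(rows):
        for key, c in counts.items():
            mat[i, key] = c
    with np.errstate(invalid="ignore"):
        d = pdist(mat, metric="cosine")
    return np.nan_to_num(d, nan=1.0)


def _profile_columns(msa_rows: List[str]) -> np.ndarray:
    """(n_columns, 20) residue frequency profile; gap cells contribute zero."""
    from .protein_sim import AMINO_ACIDS

    idx = {a: i for i, a in enumerate(AMINO_ACIDS)}
    L = len(msa_rows[0])
    prof = np.zeros((L, 20))
    for row in msa_rows:
        for c, ch in enumerate(row):
            if ch != GAP:
                prof[c, idx[ch]] += 1.0
    return prof / len(msa_rows)


def _merge_profiles(rows_a: Dict[str, str], rows_b: Dict[str, str],
                    params: PairwiseAlignmentParams) -> Dict[str, str]:
    pa = _profile_columns(list(rows_a.values()))
    pb = _profile_columns(list(rows_b.values()))
    B = _scoring_matrix(params.matrix)
    S = pa @ B @ pb.T
    _, pairs = _affine_dp(S, params.gap_open, params.gap_extend)
    merged = {}
    for k, row in rows_a.items():
        merged[k] = "".join(row[i] if i >= 0 else GAP for i, _ in pairs)
    for k, row in rows_b.items():
        merged[k] = "".join(row[j] if j >= 0 else GAP for _, j in pairs)
    return merged


def builtin_progressive_align(
    sequences: Mapping[str, str],
    params: PairwiseAlignmentParams = PairwiseAlignmentParams(),
) -> Dict[str, str]:
    """Dependency-free deterministic progressive aligner.

    UPGMA guide tree on k-mer cosine distances, then profile-profile
    affine Needleman-Wunsch merges in guide-tree order.  Intended as the
    package's built-in reference aligner for end-to-end runs, not as a
    competitor to production MSA tools.
    """
    labels = list(sequences)
    if len(labels) < 2:
        return {k: v for k, v in sequences.items()}
    seqs = [sequences[k] for k in labels]
    if len(labels) == 2:
        from .accuracy_metrics import pairwise_align

        a, b = pairwise_align(seqs[0], seqs[1], params)
        return {labels[0]: a, labels[1]: b}
    Z = linkage(_kmer_profile_distances(seqs), method="average")
    clusters: Dict[int, Dict[str, str]] = {
        i: {labels[i]: seqs[i]} for i in range(len(labels))
    }
    nxt = len(labels)
    for a_i, b_i, _, _ in Z:
        merged = _merge_profiles(clusters.pop(int(a_i)), clusters.pop(int(b_i)), params)
        clusters[nxt] = merged
        nxt += 1
    (msa,) = clusters.values()
    return {k: msa[k] for k in labels}


# -- running scenarios -----------------------------------------------------

_NODE_COLUMNS = [
    "scenario_id", "tree_rep", "seq_rep", "aligner", "node", "distance_to_root",
    "insertion_error", "deletion_error", "substitution_error", "accuracy",
    "length_ratio", "pairwise_alignment_length", "msa_length",
    "sp_score", "modeler_score", "tc_score", "cline_shift", "status",
]


def run_scenario(
    spec: ScenarioSpec,
    adapters: Sequence[AlignerAdapter],
    master_seed: int = 0,
    cutoff: float = 0.50,
) -> pd.DataFrame:
    """Run one scenario end to end and return node-level benchmark rows.

    For every tree replicate x sequence replicate x aligner the tip MSA is
    produced, ancestors are reconstructed on the true tree with the true
    model, and every internal node is scored against its true ancestor.
    Failed adapters yield rows with status 'failed' and missing metrics,
    never silently dropped rows.
    """
    if not adapters:
        raise ConfigurationError("at least one aligner adapter is required")
    ss = scenario_seed_sequence(master_seed, spec.scenario_id)
    children = ss.spawn(spec.n_tree_reps * (spec.n_seq_reps + 1))
    model = spec.rate_model()
    indels = spec.indel_params()
    flip_rate = max(2.0 * spec.indel_rate, 1e-6)
    rows = []
    ci = 0
    for tree_rep in range(spec.n_tree_reps):
        tree_seed = int(children[ci].generate_state(1, dtype=np.uint32)[0] % (2**31))
        ci += 1
        tree = simulate_tree(
            TreeSimParams(
                n_taxa=spec.n_taxa,
                height=spec.height,
                sampling_fraction=spec.sampling_fraction,
                birth_rate=spec.birth_rate,
                death_rate=spec.death_rate,
                seed=tree_seed,
            )
        )
        depths = node_depths(tree)
        tips = set(tree.tip_labels)
        internal = tree.internal_labels
        for seq_rep in range(spec.n_seq_reps):
            rng = np.random.default_rng(children[ci])
            ci += 1
            history = evolve(tree, model, indels, spec.root_length, rng=rng)
            ref_msa = _drop_allgap_columns(
                {t: history.true_alignment[t] for t in tree.tip_labels}
            )
            for adapter in adapters:
                base = dict(
                    scenario_id=spec.scenario_id, tree_rep=tree_rep,
                    seq_rep=seq_rep, aligner=adapter.identifier,
                )
                try:
                    msa = adapter.align(history)
                    check_degapped_identity(
                        msa, {t: history.sequences[t] for t in tips}, adapter.identifier
                    )
                    quality = score_msa(msa, ref_msa)
                    result = reconstruct(
                        msa, tree, model, cutoff=cutoff, indel_flip_rate=flip_rate
                    )
                except AdapterError:
                    for node in internal:
                        rows.append({**base, "node": node,
                                     "distance_to_root": depths[node],
                                     "status": "failed"})
                    continue
                L_msa = len(next(iter(msa.values())))
                for node in internal:
                    rec = reconstruction_accuracy(
                        result.sequences[node], history.sequences[node],
                        node_label=node, distance_to_root=depths[node],
                    )
                    rows.append({
                        **base,
                        "node": node,
                        "distance_to_root": depths[node],
                        "insertion_error": rec.insertion_error,
                        "deletion_error": rec.deletion_error,
                        "substitution_error": rec.substitution_error,
                        "accuracy": rec.accuracy,
                        "length_ratio": len(result.sequences[node])
                        / len(history.sequences[node]),
                        "pairwise_alignment_length": rec.alignment_length,
                        "msa_length": L_msa,
                        "sp_score": quality.sp_score,
                        "modeler_score": quality.modeler_score,
                        "tc_score": quality.tc_score,
                        "cline_shift": quality.cline_shift,
                        "status": "ok",
                    })
    return pd.DataFrame(rows, columns=_NODE_COLUMNS)


# -- statistics ------------------------------------------------------------


def _mww_pvalue(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Mann-Whitney-Wilcoxon p; exact by enumeration for small
    samples, normal approximation with tie correction otherwise."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if np.all(x == x[0]) and np.all(y == y[0]) and x[0] == y[0]:
        return 1.0
    if len(x) + len(y) <= 16:
        method = stats.PermutationMethod(n_resamples=20_000)
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return float(res.pvalue)


def compare_aligners(
    table: pd.DataFrame, alpha: float = 0.01
) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise win counts across scenarios, as in the study's win matrices.

    Per scenario and ordered aligner pair, node-level accuracies are compared
    with a two-sided Mann-Whitney-Wilcoxon test; Benjamini-Hochberg FDR is
    applied jointly across all scenario x pair tests; the higher-median
    aligner scores a win when the adjusted p is strictly below ``alpha``.
    Returns (win matrix, long table of per-test p-values).
    """
    ok = table[table["status"] == "ok"].dropna(subset=["accuracy"])
    aligners = sorted(ok["aligner"].unique())
    if len(aligners) < 2:
        raise ConfigurationError("need >= 2 aligners to compare")
    tests = []
    for scenario, sub in ok.groupby("scenario_id"):
        groups = {a: g["accuracy"].to_numpy() for a, g in sub.groupby("aligner")}
        for i, a in enumerate(aligners):
            for b in aligners[i + 1:]:
                if a not in groups or b not in groups:
                    continue
                p = _mww_pvalue(groups[a], groups[b])
                tests.append({
                    "scenario_id": scenario, "aligner_i": a, "aligner_j": b,
                    "median_i": float(np.median(groups[a])),
                    "median_j": float(np.median(groups[b])),
                    "pvalue": p,
                })
    pvals = pd.DataFrame(tests)
    wins = pd.DataFrame(0, index=aligners, columns=aligners, dtype=int)
    if not pvals.empty:
        pvals["p_adjusted"] = multipletests(pvals["pvalue"], method="fdr_bh")[1]
        for row in pvals.itertuples():
            if row.p_adjusted < alpha:
                if row.median_i > row.median_j:
                    wins.loc[row.aligner_i, row.aligner_j] += 1
                elif row.median_j > row.median_i:
                    wins.loc[row.aligner_j, row.aligner_i] += 1
    return wins, pvals


def depth_profile(
    table: pd.DataFrame, n_bins: int = 10, loess: bool = False
) -> pd.DataFrame:
    """Binned mean accuracy versus distance to root, per aligner.

    Equal-width bins over the observed depth range; per bin the mean, count
    and standard error of node accuracies.  With ``loess=True`` a lowess
    smooth evaluated at the bin centers is added for presentation.
    """
    ok = table[table["status"] == "ok"].dropna(subset=["accuracy"])
    if ok.empty:
        raise ConfigurationError("benchmark table holds no scored rows")
    lo = ok["distance_to_root"].min()
    hi = ok["distance_to_root"].max()
    if hi == lo:
        edges = np.array([lo - 0.5, lo + 0.5])
        n_bins = 1
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
    mids = 0.5 * (edges[:-1] + edges[1:])
    out = []
    for aligner, sub in ok.groupby("aligner"):
        which = np.clip(np.digitize(sub["distance_to_root"], edges) - 1, 0, n_bins - 1)
        smooth = None
        if loess:
            from statsmodels.nonparametric.smoothers_lowess import lowess

            sm = lowess(sub["accuracy"], sub["distance_to_root"], xvals=mids)
            smooth = np.asarray(sm, dtype=float)
        for b in range(n_bins):
            acc = sub["accuracy"].to_numpy()[which == b]
            rec = {
                "aligner": aligner, "bin": b, "depth_mid": mids[b],
                "n": len(acc),
                "mean_accuracy": float(acc.mean()) if len(acc) else np.nan,
                "se": float(acc.std(ddof=1) / np.sqrt(len(acc))) if len(acc) > 1 else np.nan,
            }
            if smooth is not None:
                rec["loess"] = float(smooth[b])
            out.append(rec)
    return pd.DataFrame(out)


def indel_bias(table: pd.DataFrame) -> pd.DataFrame:
    """Per-aligner insertion/deletion error and length-ratio summaries."""
    ok = table[table["status"] == "ok"].dropna(subset=["accuracy"])
    if ok.empty:
        raise ConfigurationError("benchmark table holds no scored rows")
    agg = ok.groupby("aligner").agg(
        mean_insertion_error=("insertion_error", "mean"),
        median_insertion_error=("insertion_error", "median"),
        mean_deletion_error=("deletion_error", "mean"),
        median_deletion_error=("deletion_error", "median"),
        mean_length_ratio=("length_ratio", "mean"),
        median_length_ratio=("length_ratio", "median"),
        n=("accuracy", "size"),
    )
    return agg.reset_index()


def quality_vs_accuracy(table: pd.DataFrame) -> pd.DataFrame:
    """Correlations between MSA quality scores and reconstruction accuracy.

    Observations are scenario means (accuracy averaged over all nodes and
    replicates; quality averaged over replicates), computed per aligner and
    pooled across aligners.  Pearson r, r^2 and Spearman rho are reported;
    zero-variance inputs are flagged as undefined rather than propagating
    NaNs.
    """
    ok = table[table["status"] == "ok"].dropna(subset=["accuracy"])
    means = ok.groupby(["scenario_id", "aligner"]).agg(
        accuracy=("accuracy", "mean"),
        **{m: (m, "mean") for m in QUALITY_METRICS},
    ).reset_index()
    out = []

    def corr_rows(label: str, sub: pd.DataFrame):
        for metric in QUALITY_METRICS:
            x = sub[metric].to_numpy(dtype=float)
            y = sub["accuracy"].to_numpy(dtype=float)
            rec = {"aligner": label, "metric": metric, "n": len(x)}
            if len(x) < 3 or np.ptp(x) == 0 or np.ptp(y) == 0:
                rec.update(defined=False, pearson_r=np.nan, r2=np.nan, spearman_rho=np.nan)
            else:
                r = stats.pearsonr(x, y).statistic
                rho = stats.spearmanr(x, y).statistic
                rec.update(defined=True, pearson_r=float(r), r2=float(r * r),
                           spearman_rho=float(rho))
            out.append(rec)

    for aligner, sub in means.groupby("aligner"):
        corr_rows(aligner, sub)
    corr_rows("pooled", means)
    return pd.DataFrame(out)
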