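"""Synthetic inputs with known truth: sequences, environments, occurrences.

Sequence data come from a structured coalescent without migration: each
population coalesces internally (Kingman, haploid/mtDNA convention — the
relevant effective size is the female effective size), surviving lineages
merge into the ancestral population at the split times, and mutations are
applied by evolving sites down the genealogy under a reversible substitution
model (Jukes-Cantor by default, TN93 optionally).  Time is measured in
million years; with a per-lineage mutation rate ``mu`` (substitutions per
site per My) a split ``T`` My ago yields an expected net between-group
distance of 2*mu*T, i.e. T = D / 0.02 under the conventional 2%/My
between-lineage mitochondrial clock with mu = 0.01.

Environment layers are smooth Gaussian-ish random fields built by repeated
box-blur of white noise; occurrences are drawn from a known logistic
suitability truth, which makes identical-niche pairs (shared coefficients)
available for null calibration of the overlap tests.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.linalg import expm
from scipy.ndimage import uniform_filter

from ._errors import ValidationError
from .alignment import Alignment, PopulationAssignment
from .enm import EnvStack, OccurrenceSet, write_ascii_grid, write_occurrences

__all__ = [
    "PopModel",
    "NicheTruth",
    "simulate_sequences",
    "simulate_env",
    "true_suitability",
    "simulate_occurrences",
    "make_benchmark_suite",
]

_BASES = np.array(["A", "C", "G", "T"])


@dataclass
class PopModel:
    """Population-split model for the coalescent simulator.

    ``split_tree`` is either a population label (leaf) or a tuple
    ``(time_My, left, right)``; internal times must exceed their children's.
    ``coalescent_scale`` is the within-deme coalescent time scale N_f * g in
    My (applies to ancestral demes too); ``mutation_rate`` is per lineage,
    substitutions/site/My.
    """

    split_tree: object
    samples_per_pop: dict[str, int]
    sequence_length: int = 2000
    coalescent_scale: float = 0.05
    mutation_rate: float = 0.01
    mutation_model: str = "jc"
    base_freqs: tuple = (0.25, 0.25, 0.25, 0.25)
    kappa1: float = 4.0  # A<->G transition/transversion rate ratio (TN93)
    kappa2: float = 4.0  # C<->T
    seed: int | None = None

    def leaf_names(self) -> list[str]:
        names: list[str] = []

        def walk(node):
            if isinstance(node, tuple):
                _, left, right = node
                walk(left)
                walk(right)
            else:
                names.append(node)

        walk(self.split_tree)
        return names

    def validate(self) -> None:
        if self.sequence_length <= 0:
            raise ValidationError("sequence_length must be positive")
        if self.coalescent_scale <= 0 or self.mutation_rate <= 0:
            raise ValidationError("scales must be positive")
        leaves = self.leaf_names()
        if len(leaves) != len(set(leaves)):
            raise ValidationError("duplicate population labels in split_tree")
        missing = [p for p in leaves if p not in self.samples_per_pop]
        if missing:
            raise ValidationError(f"populations without sample sizes: {missing}")

        def check(node, parent_time):
            if isinstance(node, tuple):
                t, left, right = node
                if t <= 0:
                    raise ValidationError("split times must be positive")
                if parent_time is not None and t >= parent_time:
                    raise ValidationError(
                        "child split time must be younger than its parent's"
                    )
                check(left, t)
                check(right, t)

        check(self.split_tree, None)


def _rate_matrix(model: PopModel) -> np.ndarray:
    """Reversible rate matrix normalized to one expected substitution per
    unit (mu * t) of branch length."""
    pi = np.asarray(model.base_freqs, dtype=float)
    pi = pi / pi.sum()
    if model.mutation_model == "jc":
        Q = np.full((4, 4), 1.0 / 3.0)
    elif model.mutation_model == "tn93":
        # order A, C, G, T; transitions A<->G (kappa1), C<->T (kappa2)
        Q = np.ones((4, 4))
        Q[0, 2] = Q[2, 0] = model.kappa1
        Q[1, 3] = Q[3, 1] = model.kappa2
        Q = Q * pi[None, :]
    else:
        raise ValidationError(f"unknown mutation_model: {model.mutation_model!r}")
    if model.mutation_model == "jc":
        pi = np.full(4, 0.25)
    np.fill_diagonal(Q, 0.0)
    np.fill_diagonal(Q, -Q.sum(axis=1))
    rate = -np.sum(pi * np.diag(Q))
    return Q / rate


def _simulate_genealogy(model: PopModel, rng) -> tuple[dict, list[tuple[str, str]]]:
    """Structured coalescent on the split tree.

    Returns (nodes, tips): nodes maps node_id -> (time, parent_id or None);
    tips is [(node_id, population)] in sampling order.
    """
    nu = model.coalescent_scale
    counter = [0]
    nodes: dict[int, list] = {}  # id -> [time, parent]
    tips: list[tuple[int, str]] = []

    def new_node(t):
        counter[0] += 1
        nodes[counter[0]] = [t, None]
        return counter[0]

    def coalesce(lineages: list[int], t_start: float, t_end: float) -> list[int]:
        t = t_start
        lineages = list(lineages)
        while len(lineages) > 1:
            k = len(lineages)
            dt = rng.exponential(nu / (k * (k - 1) / 2.0))
            if t + dt >= t_end:
                return lineages
            t += dt
            i, j = rng.choice(k, size=2, replace=False)
            parent = new_node(t)
            nodes[lineages[i]][1] = parent
            nodes[lineages[j]][1] = parent
            lineages = [l for idx, l in enumerate(lineages) if idx not in (i, j)]
            lineages.append(parent)
        return lineages

    def walk(node, parent_time: float) -> list[int]:
        if isinstance(node, tuple):
            t_split, left, right = node
            survivors = walk(left, t_split) + walk(right, t_split)
            return coalesce(survivors, t_split, parent_time)
        pop = node
        lineages = []
        for _ in range(model.samples_per_pop[pop]):
            nid = new_node(0.0)
            tips.append((nid, pop))
            lineages.append(nid)
        return coalesce(lineages, 0.0, parent_time)

    roots = walk(model.split_tree, np.inf)
    assert len(roots) == 1
    return {k: tuple(v) for k, v in nodes.items()}, tips


def simulate_sequences(model: PopModel) -> tuple[Alignment, PopulationAssignment, dict]:
    """Simulate an alignment under the split model.

    Returns (alignment, population assignment, truth record) where the truth
    record carries the split tree, per-site theta and the seed actually used.
    """
    model.validate()
    rng = np.random.default_rng(model.seed)
    nodes, tips = _simulate_genealogy(model, rng)
    Q = _rate_matrix(model)
    pi = (np.full(4, 0.25) if model.mutation_model == "jc"
          else np.asarray(model.base_freqs) / np.sum(model.base_freqs))

    children: dict[int | None, list[int]] = {}
    for nid, (t, parent) in nodes.items():
        children.setdefault(parent, []).append(nid)
    (root,) = children[None]

    L = model.sequence_length
    seqs: dict[int, np.ndarray] = {root: rng.choice(4, size=L, p=pi)}
    stack = [root]
    while stack:
        parent = stack.pop()
        t_parent = nodes[parent][0]
        for child in children.get(parent, []):
            blen = t_parent - nodes[child][0]
            P = expm(Q * model.mutation_rate * blen)
            P = np.clip(P, 0.0, None)
            P /= P.sum(axis=1, keepdims=True)
            parent_seq = seqs[parent]
            child_seq = np.empty(L, dtype=np.int64)
            u = rng.uniform(size=L)
            cum = np.cumsum(P, axis=1)
            child_seq = (u[:, None] > cum[parent_seq]).sum(axis=1)
            seqs[child] = child_seq
            stack.append(child)

    sample_ids, rows, s2p = [], [], {}
    pop_counter: dict[str, int] = {}
    for nid, pop in tips:
        pop_counter[pop] = pop_counter.get(pop, 0) + 1
        sid = f"{pop}_{pop_counter[pop]:02d}"
        sample_ids.append(sid)
        rows.append(_BASES[seqs[nid]])
        s2p[sid] = pop
    aln = Alignment(sample_ids, np.array(rows), "simulated")
    truth = {
        "split_tree": repr(model.split_tree),
        "theta_per_site": 2.0 * model.coalescent_scale * model.mutation_rate,
        "mutation_rate": model.mutation_rate,
        "coalescent_scale": model.coalescent_scale,
        "sequence_length": L,
        "mutation_model": model.mutation_model,
        "seed": model.seed,
    }
    return aln, PopulationAssignment(s2p), truth


# ---------------------------------------------------------------------------
# environments and occurrences


@dataclass
class NicheTruth:
    """Grid spec, layer generators and the true suitability coefficients.

    ``lineage_coefs`` maps lineage -> (alpha, {layer: beta}); the true
    suitability is logistic(alpha + sum beta_k * layer_k).  Identical-niche
    pairs share a coefficient entry exactly.
    """

    nrows: int = 100
    ncols: int = 100
    xllcorner: float = 0.0
    yllcorner: float = 0.0
    cellsize: float = 0.1
    n_layers: int = 3
    n_noise_layers: int = 0
    correlation_length: int = 5
    blur_passes: int = 3
    duplicate_layer: bool = False
    duplicate_noise_sd: float = 0.05
    # default: a narrow-band specialist occupying roughly the top decile of
    # the env1 gradient (suitability 0.5 at z = 1.25)
    lineage_coefs: dict = field(
        default_factory=lambda: {"A": (-10.0, {"env1": 8.0})}
    )
    seed: int | None = None


def simulate_env(truth: NicheTruth) -> EnvStack:
    """Smooth correlated layers (repeated box-blur of white noise, kernel
    width = 2*correlation_length + 1, ``blur_passes`` passes), each
    standardized to mean 0 / sd 1 over the grid; optional pure-noise layers
    and an optional near-duplicate of the first layer for pruning tests."""
    rng = np.random.default_rng(truth.seed)
    layers: dict[str, np.ndarray] = {}
    size = 2 * truth.correlation_length + 1
    for i in range(truth.n_layers):
        f = rng.normal(size=(truth.nrows, truth.ncols))
        if truth.correlation_length > 0:
            for _ in range(truth.blur_passes):
                f = uniform_filter(f, size=size, mode="wrap")
        f = (f - f.mean()) / f.std()
        layers[f"env{i + 1}"] = f
    for i in range(truth.n_noise_layers):
        f = rng.normal(size=(truth.nrows, truth.ncols))
        layers[f"noise{i + 1}"] = (f - f.mean()) / f.std()
    if truth.duplicate_layer:
        f = layers["env1"] + rng.normal(0, truth.duplicate_noise_sd,
                                        size=(truth.nrows, truth.ncols))
        layers["env1_dup"] = (f - f.mean()) / f.std()
    return EnvStack.from_layers(layers, truth.xllcorner, truth.yllcorner,
                                truth.cellsize)


def true_suitability(truth: NicheTruth, env: EnvStack, lineage: str) -> np.ndarray:
    """logistic(alpha + sum beta * layer) over the grid (masked cells 0)."""
    if lineage not in truth.lineage_coefs:
        raise ValidationError(f"unknown lineage {lineage!r}")
    alpha, betas = truth.lineage_coefs[lineage]
    eta = np.full((env.nrows, env.ncols), float(alpha))
    for name, beta in betas.items():
        eta += beta * env.layer(name)
    p = 1.0 / (1.0 + np.exp(-eta))
    return np.where(env.mask, p, 0.0)


def simulate_occurrences(
    truth: NicheTruth,
    env: EnvStack,
    lineage: str,
    n: int,
    region: np.ndarray | None = None,
    seed: int | None = None,
) -> OccurrenceSet:
    """Sample n presence points: cells with probability proportional to true
    suitability (within an optional boolean region), jittered uniformly
    within the cell."""
    rng = np.random.default_rng(seed)
    suit = true_suitability(truth, env, lineage)
    mask = env.mask if region is None else (env.mask & np.asarray(region, dtype=bool))
    if not mask.any():
        raise ValidationError("region does not overlap the grid mask")
    cells = np.argwhere(mask)
    weights = suit[mask]
    total = weights.sum()
    if total <= 0:
        raise ValidationError("region has zero total suitability")
    chosen = cells[rng.choice(len(cells), size=n, p=weights / total)]
    jitter = rng.uniform(0, 1, size=(n, 2))
    lon = env.xllcorner + (chosen[:, 1] + jitter[:, 0]) * env.cellsize
    lat = env.yllcorner + (env.nrows - chosen[:, 0] - jitter[:, 1]) * env.cellsize
    return OccurrenceSet(np.column_stack([lon, lat]), source=f"sim:{lineage}")


# ---------------------------------------------------------------------------
# benchmark fixture suite


def make_benchmark_suite(outdir, seed: int = 0) -> dict:
    """Write a small fixed fixture set (FASTA, assignment TSVs, ASCII grids,
    occurrence CSVs) plus a manifest of the true parameters.  Bit-identical
    under the same seed."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)

    # two-group, four-population sequence data with a deep primary split
    split_tree = (1.0, (0.2, "pop1", "pop2"), (0.2, "pop3", "pop4"))
    model = PopModel(
        split_tree=split_tree,
        samples_per_pop={p: 8 for p in ("pop1", "pop2", "pop3", "pop4")},
        sequence_length=1500,
        seed=int(rng.integers(2**31)),
    )
    aln, pops, seq_truth = simulate_sequences(model)
    from .alignment import write_fasta_alignment

    write_fasta_alignment(aln, out / "sequences.fasta")
    with open(out / "populations.tsv", "w") as fh:
        for sid in aln.sample_ids:
            fh.write(f"{sid}\t{pops.sample_to_pop[sid]}\n")
    groups = {"pop1": "west", "pop2": "west", "pop3": "east", "pop4": "east"}
    with open(out / "groups.tsv", "w") as fh:
        for pop, grp in groups.items():
            fh.write(f"{pop}\t{grp}\n")

    # environment + occurrences: two identical-niche lineages, one shifted
    truth = NicheTruth(
        nrows=60, ncols=60, cellsize=0.1, n_layers=3,
        lineage_coefs={
            "A": (0.0, {"env1": 2.5}),
            "B": (0.0, {"env1": 2.5}),        # identical niche to A
            "C": (0.0, {"env2": 2.5}),        # shifted niche
        },
        seed=int(rng.integers(2**31)),
    )
    env = simulate_env(truth)
    for name in env.names:
        write_ascii_grid(out / f"{name}.asc", env.layer(name), env.xllcorner,
                         env.yllcorner, env.cellsize)
    occ_seeds = {}
    for lineage in ("A", "B", "C"):
        s = int(rng.integers(2**31))
        occ_seeds[lineage] = s
        occ = simulate_occurrences(truth, env, lineage, n=40, seed=s)
        write_occurrences(occ, out / f"occurrences_{lineage}.csv")

    manifest = {
        "seed": seed,
        "sequences": seq_truth,
        "groups": groups,
        "niche": {
            "grid": [truth.nrows, truth.ncols],
            "cellsize": truth.cellsize,
            "lineage_coefs": {
                k: [a, dict(b)] for k, (a, b) in truth.lineage_coefs.items()
            },
            "occurrence_seeds": occ_seeds,
            "env_seed": truth.seed,
        },
        "true_split_times_My": {"primary": 1.0, "secondary": 0.2},
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    digest = hashlib.sha256()
    for p in sorted(out.iterdir()):
        if p.name != "checksum.txt":
            digest.update(p.name.encode())
            digest.update(p.read_bytes())
    (out / "checksum.txt").write_text(digest.hexdigest() + "\n")
    return manifest
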