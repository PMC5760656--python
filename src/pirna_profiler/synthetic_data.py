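"""Scenario simulator: references, small-RNA libraries, and truth tables.

The generator emulates the statistical structure of adult-testis small-RNA
libraries so every pipeline stage can be verified at desk scale:

* a heavy-tailed (power-law) per-cluster abundance spectrum in which a top
  subset of clusters dominates total piRNA output;
* spiky within-cluster read-start distributions (a Dirichlet-weighted hotspot
  mixture over a uniform background);
* a bimodal read-length mixture — 25-28 nt MILI-like and 29-32 nt MIWI-like
  components with peaked within-range weights;
* a strong first-nucleotide U bias (position 1 is U with probability
  ``u1_prob`` exactly);
* 21-23 nt miRNA-proxy reads whose abundance is genotype-independent by
  construction;
* knockout genotypes implemented as binomial read thinning, so recovery
  bounds are exact binomial statements: ``uniform_depletion`` thins every
  cluster read by ``1/factor``; ``five_prime_sparing`` thins only reads
  starting at or beyond ``window_nt`` in the ``top_k`` most abundant
  clusters, sparing the precursor 5' ends;
* CLIP fragments >= 15 nt with a first-nucleotide A bias and density either
  proportional to the piRNA start model or uniform.

Every read is recorded in a truth table; identical seed and configuration
produce byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .annotate import DEFAULT_CATEGORY_ORDER, CategoryHierarchy
from .io_preprocess import SmallRNARead, write_sequences

CLUSTER_CATEGORY = "piRNA_clusters"
NONCLUSTER_CATEGORIES = ("coding_RNA", "noncoding_RNA", "repeats", "intron")
OTHER = "other"
MIRNA = "miRNA"

#: Illumina small-RNA 3' adapter, appended to simulated FASTQ reads
DEFAULT_ADAPTER = "TGGAATTCTCGGGTGCCAAGG"

_NTS = np.frombuffer(b"ACGT", dtype="S1")

# rng stream keys: one top-level seed, fixed per-stage spawn keys
_STREAMS = {"reference": 1, "library": 2, "genotype": 3, "clip": 4}


def _rng(seed: int, stream: str) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), _STREAMS[stream]]))


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_NTS, size=length).tobytes().decode()


@dataclass(frozen=True)
class LengthMixture:
    """Bimodal mature-read length model (MILI-like + MIWI-like components).

    Within-range weights are peaked so the simulated size distribution has
    interior modes, as real libraries do, rather than flat plateaus.
    """

    mili_lengths: tuple[int, ...] = (25, 26, 27, 28)
    mili_weights: tuple[float, ...] = (0.15, 0.35, 0.35, 0.15)
    miwi_lengths: tuple[int, ...] = (29, 30, 31, 32)
    miwi_weights: tuple[float, ...] = (0.15, 0.35, 0.35, 0.15)
    mili_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.mili_fraction <= 1.0:
            raise ValueError("mili_fraction must be in [0, 1]")
        for w in (self.mili_weights, self.miwi_weights):
            if abs(sum(w) - 1.0) > 1e-9:
                raise ValueError("length weights must sum to 1")

    def sample(self, rng: np.random.Generator, n: int) -> tuple[np.ndarray, np.ndarray]:
        """Draw ``n`` lengths; returns (lengths, is_mili_component)."""
        is_mili = rng.random(n) < self.mili_fraction
        lengths = np.empty(n, dtype=int)
        n_mili = int(is_mili.sum())
        lengths[is_mili] = rng.choice(self.mili_lengths, size=n_mili, p=self.mili_weights)
        lengths[~is_mili] = rng.choice(
            self.miwi_lengths, size=n - n_mili, p=self.miwi_weights
        )
        return lengths, is_mili

    @property
    def max_length(self) -> int:
        return max(self.mili_lengths + self.miwi_lengths)


@dataclass(frozen=True)
class HotspotModel:
    """Within-cluster read-start model: Dirichlet hotspots + uniform background."""

    n_hotspots: int = 50
    dirichlet_alpha: float = 0.3
    background_fraction: float = 0.1

    def __post_init__(self) -> None:
        if not 0.0 <= self.background_fraction <= 1.0:
            raise ValueError("background_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GenotypeModel:
    """Genotype transform applied to cluster-derived reads by binomial thinning."""

    kind: str = "WT"  # WT | uniform_depletion | five_prime_sparing
    factor: float = 1.0
    window_nt: int = 300
    top_k: int = 0
    miwi_global_factor: float = 1.0

    def __post_init__(self) -> None:
        if self.kind not in ("WT", "uniform_depletion", "five_prime_sparing"):
            raise ValueError(f"unknown genotype kind {self.kind!r}")
        if self.factor < 1.0 or self.miwi_global_factor < 1.0:
            raise ValueError("thinning factors must be >= 1")
        if self.window_nt < 0:
            raise ValueError("window_nt must be >= 0")

    @staticmethod
    def wildtype() -> "GenotypeModel":
        return GenotypeModel()

    @staticmethod
    def uniform_depletion(factor: float) -> "GenotypeModel":
        return GenotypeModel(kind="uniform_depletion", factor=factor)

    @staticmethod
    def five_prime_sparing(
        window_nt: int = 300,
        factor: float = 7.0,
        top_k: int = 50,
        miwi_global_factor: float = 1.0,
    ) -> "GenotypeModel":
        return GenotypeModel(
            kind="five_prime_sparing",
            factor=factor,
            window_nt=window_nt,
            top_k=top_k,
            miwi_global_factor=miwi_global_factor,
        )


@dataclass(frozen=True)
class ClipConfig:
    """CLIP-fragment simulation settings."""

    enabled: bool = True
    n_reads: int = 50_000
    min_len: int = 15
    max_len: int = 50
    a1_prob: float = 0.5
    density_source: str = "proportional"  # proportional | uniform

    def __post_init__(self) -> None:
        if not 1 <= self.min_len <= self.max_len:
            raise ValueError("need 1 <= min_len <= max_len")
        if not 0.0 <= self.a1_prob <= 1.0:
            raise ValueError("a1_prob must be in [0, 1]")
        if self.density_source not in ("proportional", "uniform"):
            raise ValueError(f"unknown density_source {self.density_source!r}")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full parameterization of the synthetic genome, libraries and genotype.

    Defaults describe the full-size study conditions (214 clusters of
    2-20 kb, 80% of window reads cluster-derived); :meth:`desk` returns the
    scaled-down preset (20 clusters of 0.5-2 kb, 50,000 window reads) used
    for fast end-to-end verification.
    """

    seed: int = 0
    n_clusters: int = 214
    cluster_length_range: tuple[int, int] = (2_000, 20_000)
    abundance_exponent: float = 1.5
    total_cluster_reads: int = 1_000_000
    noncluster_reads: Mapping[str, int] = field(
        default_factory=lambda: {
            "coding_RNA": 60_000,
            "noncoding_RNA": 40_000,
            "repeats": 80_000,
            "intron": 50_000,
            "other": 20_000,
        }
    )
    noncluster_seqs_per_category: int = 5
    noncluster_seq_length_range: tuple[int, int] = (800, 1_500)
    mirna_reads: int = 200_000
    u1_prob: float = 0.8
    length_mixture: LengthMixture = field(default_factory=LengthMixture)
    hotspots: HotspotModel = field(default_factory=HotspotModel)
    genotype: GenotypeModel = field(default_factory=GenotypeModel)
    clip: ClipConfig = field(default_factory=ClipConfig)
    adapter: str = DEFAULT_ADAPTER

    def __post_init__(self) -> None:
        if not 0.0 <= self.u1_prob <= 1.0:
            raise ValueError("u1_prob must be in [0, 1]")
        lo, hi = self.cluster_length_range
        if lo > hi or lo < self.length_mixture.max_length + 1:
            raise ValueError(f"invalid cluster_length_range ({lo}, {hi})")
        if self.genotype.top_k > self.n_clusters:
            raise ValueError("genotype top_k exceeds n_clusters")

    @staticmethod
    def desk(seed: int = 0, genotype: Optional[GenotypeModel] = None) -> "ScenarioConfig":
        """Scaled-down preset: the full pipeline runs in well under a minute."""
        return ScenarioConfig(
            seed=seed,
            n_clusters=20,
            cluster_length_range=(500, 2_000),
            total_cluster_reads=40_000,
            noncluster_reads={
                "coding_RNA": 3_000,
                "noncoding_RNA": 1_500,
                "repeats": 2_500,
                "intron": 2_000,
                "other": 1_000,
            },
            mirna_reads=8_000,
            genotype=genotype or GenotypeModel.five_prime_sparing(300, 7.0, 10),
            clip=ClipConfig(n_reads=50_000),
        )

    # -- serialization ------------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noncluster_reads"] = dict(self.noncluster_reads)
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "ScenarioConfig":
        d = dict(d)
        for key, sub in (
            ("length_mixture", LengthMixture),
            ("hotspots", HotspotModel),
            ("genotype", GenotypeModel),
            ("clip", ClipConfig),
        ):
            if key in d and isinstance(d[key], Mapping):
                payload = {
                    k: tuple(v) if isinstance(v, list) else v for k, v in d[key].items()
                }
                d[key] = sub(**payload)
        for key in ("cluster_length_range", "noncluster_seq_length_range"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ScenarioConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))


@dataclass
class Reference:
    """Synthetic reference: cluster and category sequences plus hotspot tables.

    ``clusters`` is ordered by true abundance (first cluster most abundant);
    ``abundance`` holds the per-cluster sampling weights.
    """

    clusters: dict[str, str]
    categories: dict[str, dict[str, str]]
    hotspot_positions: dict[str, np.ndarray]
    hotspot_weights: dict[str, np.ndarray]
    abundance: dict[str, float]

    @property
    def cluster_order(self) -> list[str]:
        return list(self.clusters)

    def cluster_lengths(self) -> dict[str, int]:
        return {name: len(seq) for name, seq in self.clusters.items()}

    def to_hierarchy(self) -> CategoryHierarchy:
        cats = [(CLUSTER_CATEGORY, self.clusters)]
        cats += [(name, self.categories[name]) for name in NONCLUSTER_CATEGORIES]
        return CategoryHierarchy(cats)

    def write(self, outdir: str | Path) -> dict[str, Path]:
        """Write category FASTAs, a cluster BED, and a hierarchy YAML."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths: dict[str, Path] = {}
        entries = []
        for cat, targets in [(CLUSTER_CATEGORY, self.clusters)] + [
            (name, self.categories[name]) for name in NONCLUSTER_CATEGORIES
        ]:
            fasta = outdir / f"{cat}.fa"
            write_sequences(
                [SmallRNARead(name, seq) for name, seq in targets.items()], fasta
            )
            paths[cat] = fasta
            entries.append({"name": cat, "fasta": fasta.name})
        bed = outdir / "clusters.bed"
        with open(bed, "w") as fh:
            for name, seq in self.clusters.items():
                fh.write(f"{name}\t0\t{len(seq)}\t{name}\t0\t+\n")
        paths["clusters_bed"] = bed
        hier = outdir / "hierarchy.yaml"
        hier.write_text(yaml.safe_dump({"fallthrough": OTHER, "categories": entries}))
        paths["hierarchy"] = hier
        return paths


def make_reference(cfg: ScenarioConfig) -> Reference:
    """Generate seeded random reference sequences and hotspot tables."""
    rng = _rng(cfg.seed, "reference")
    width = len(str(cfg.n_clusters))
    max_read = cfg.length_mixture.max_length
    clusters: dict[str, str] = {}
    seen: set[str] = set()
    lengths = rng.integers(
        cfg.cluster_length_range[0], cfg.cluster_length_range[1] + 1, size=cfg.n_clusters
    )
    for i, L in enumerate(lengths):
        name = f"cluster_{i + 1:0{width}d}"
        seq = _random_seq(rng, int(L))
        while seq in seen:  # vanishingly unlikely; re-draw on collision
            seq = _random_seq(rng, int(L))
        seen.add(seq)
        clusters[name] = seq
    categories: dict[str, dict[str, str]] = {}
    lo, hi = cfg.noncluster_seq_length_range
    for cat in NONCLUSTER_CATEGORIES:
        targets = {}
        for j in range(cfg.noncluster_seqs_per_category):
            seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            while seq in seen:
                seq = _random_seq(rng, int(rng.integers(lo, hi + 1)))
            seen.add(seq)
            targets[f"{cat}_{j + 1:02d}"] = seq
        categories[cat] = targets
    hotspot_positions: dict[str, np.ndarray] = {}
    hotspot_weights: dict[str, np.ndarray] = {}
    for name, seq in clusters.items():
        max_start = len(seq) - max_read - 1
        hotspot_positions[name] = rng.integers(
            0, max_start + 1, size=cfg.hotspots.n_hotspots
        )
        hotspot_weights[name] = rng.dirichlet(
            np.full(cfg.hotspots.n_hotspots, cfg.hotspots.dirichlet_alpha)
        )
    ranks = np.arange(1, cfg.n_clusters + 1, dtype=float)
    weights = ranks ** -cfg.abundance_exponent
    weights /= weights.sum()
    abundance = dict(zip(clusters, weights))
    return Reference(clusters, categories, hotspot_positions, hotspot_weights, abundance)


@dataclass
class SimulatedLibrary:
    """One simulated library: reads (adapter-free inserts) plus its truth table.

    Truth columns: ``read_id``, ``category``, ``cluster`` (empty for
    non-cluster reads), ``true_start`` (-1 for non-cluster reads), ``length``,
    ``length_class`` (MILI/MIWI/miRNA/other).
    """

    label: str
    reads: list[SmallRNARead]
    truth: pd.DataFrame
    genotype: GenotypeModel

    def to_fastq(self, path: str | Path, adapter: str = "") -> None:
        """Write 4-line FASTQ; when ``adapter`` is given it is appended to
        every read, emulating 3' adapter read-through."""
        with open(path, "w") as fh:
            for r in self.reads:
                seq = r.seq + adapter
                fh.write(f"@{r.read_id}\n{seq}\n+\n{'I' * len(seq)}\n")

    def truth_to_tsv(self, path: str | Path) -> None:
        self.truth.to_csv(path, sep="\t", index=False)


def _sample_cluster_starts(
    rng: np.random.Generator,
    reference: Reference,
    cluster: str,
    n: int,
    background_fraction: float,
) -> np.ndarray:
    L = len(reference.clusters[cluster])
    max_start = L - 33  # leave room for the longest mature read
    starts = np.empty(n, dtype=int)
    is_bg = rng.random(n) < background_fraction
    n_bg = int(is_bg.sum())
    starts[is_bg] = rng.integers(0, max_start + 1, size=n_bg)
    idx = rng.choice(
        len(reference.hotspot_positions[cluster]),
        size=n - n_bg,
        p=reference.hotspot_weights[cluster],
    )
    starts[~is_bg] = reference.hotspot_positions[cluster][idx]
    return starts


def _apply_first_nt_bias(
    rng: np.random.Generator, seqs: list[str], nt: str, prob: float
) -> list[str]:
    """Overwrite position 1: the biased base with probability ``prob``, else a
    uniform draw over the remaining three bases — so the measured first-
    nucleotide fraction is exactly Bernoulli(``prob``)."""
    others = [b for b in "ACGT" if b != nt]
    hit = rng.random(len(seqs)) < prob
    alt = rng.choice(np.frombuffer("".join(others).encode(), dtype="S1"), size=len(seqs))
    return [
        (nt if h else alt[i].decode()) + s[1:] for i, (s, h) in enumerate(zip(seqs, hit))
    ]


def simulate_library(
    cfg: ScenarioConfig, reference: Optional[Reference] = None, label: str = "WT"
) -> SimulatedLibrary:
    """Draw the base (wild-type) library under the scenario's models."""
    reference = reference or make_reference(cfg)
    rng = _rng(cfg.seed, "library")
    mix = cfg.length_mixture
    ids: list[str] = []
    seqs: list[str] = []
    rows: list[tuple] = []
    serial = 0

    def _emit(category: str, cluster: str, start: int, seq: str, lclass: str) -> None:
        nonlocal serial
        rid = f"sim:{serial:07d}"
        serial += 1
        ids.append(rid)
        seqs.append(seq)
        rows.append((rid, category, cluster, start, len(seq), lclass))

    # cluster-derived piRNAs: heavy-tailed abundance, hotspot starts
    p = np.array([reference.abundance[c] for c in reference.cluster_order])
    per_cluster = rng.multinomial(cfg.total_cluster_reads, p)
    for cluster, n_i in zip(reference.cluster_order, per_cluster):
        if n_i == 0:
            continue
        cseq = reference.clusters[cluster]
        starts = _sample_cluster_starts(
            rng, reference, cluster, int(n_i), cfg.hotspots.background_fraction
        )
        lengths, is_mili = mix.sample(rng, int(n_i))
        raw = [cseq[s : s + l] for s, l in zip(starts, lengths)]
        raw = _apply_first_nt_bias(rng, raw, "T", cfg.u1_prob)
        for s, l, m, seq in zip(starts, lengths, is_mili, raw):
            _emit(
                CLUSTER_CATEGORY, cluster, int(s), seq, "MILI" if m else "MIWI"
            )
    # non-cluster piRNA sources (genotype-independent)
    for cat in NONCLUSTER_CATEGORIES:
        n_cat = cfg.noncluster_reads.get(cat, 0)
        if n_cat == 0:
            continue
        names = list(reference.categories[cat])
        tidx = rng.integers(0, len(names), size=n_cat)
        lengths, is_mili = mix.sample(rng, n_cat)
        raw = []
        starts = []
        for ti, l in zip(tidx, lengths):
            tseq = reference.categories[cat][names[ti]]
            s = int(rng.integers(0, len(tseq) - mix.max_length))
            starts.append(s)
            raw.append(tseq[s : s + l])
        raw = _apply_first_nt_bias(rng, raw, "T", cfg.u1_prob)
        for s, l, m, seq in zip(starts, lengths, is_mili, raw):
            _emit(cat, "", -1, seq, "MILI" if m else "MIWI")
    # unannotatable reads ("other"): random sequence, window lengths
    n_other = cfg.noncluster_reads.get(OTHER, 0)
    if n_other:
        lengths, _ = mix.sample(rng, n_other)
        for l in lengths:
            _emit(OTHER, "", -1, _random_seq(rng, int(l)), OTHER)
    # miRNA proxy: 21-23 nt, genotype-independent reference population
    if cfg.mirna_reads:
        lengths = rng.integers(21, 24, size=cfg.mirna_reads)
        for l in lengths:
            _emit(MIRNA, "", -1, _random_seq(rng, int(l)), MIRNA)

    order = rng.permutation(len(ids))
    truth = pd.DataFrame(
        rows, columns=["read_id", "category", "cluster", "true_start", "length", "length_class"]
    ).iloc[order].reset_index(drop=True)
    reads = [SmallRNARead(ids[i], seqs[i], source="simulated") for i in order]
    return SimulatedLibrary(label, reads, truth, GenotypeModel.wildtype())


def apply_genotype(
    base: SimulatedLibrary,
    genotype: GenotypeModel,
    cfg: ScenarioConfig,
    reference: Reference,
    label: Optional[str] = None,
) -> SimulatedLibrary:
    """Thin the base library per the genotype model (paired-design knockout).

    Thinning is binomial with retention ``1/factor`` on the affected read
    set; miRNA-proxy and non-cluster reads are never touched, so paired
    normalization factors and non-cluster abundances are genotype-invariant
    by construction.
    """
    rng = _rng(cfg.seed, "genotype")
    truth = base.truth
    n = len(truth)
    keep = np.ones(n, dtype=bool)
    is_cluster = (truth["category"] == CLUSTER_CATEGORY).to_numpy()
    if genotype.kind == "uniform_depletion":
        u = rng.random(n)
        keep &= ~is_cluster | (u < 1.0 / genotype.factor)
    elif genotype.kind == "five_prime_sparing":
        if genotype.window_nt >= min(len(s) for s in reference.clusters.values()):
            import warnings

            warnings.warn("sparing window covers entire shortest cluster")
        top = set(reference.cluster_order[: genotype.top_k])
        affected = (
            is_cluster
            & truth["cluster"].isin(top).to_numpy()
            & (truth["true_start"].to_numpy() >= genotype.window_nt)
        )
        u = rng.random(n)
        keep &= ~affected | (u < 1.0 / genotype.factor)
        if genotype.miwi_global_factor > 1.0:
            miwi = (truth["length_class"] == "MIWI").to_numpy()
            u2 = rng.random(n)
            keep &= ~miwi | (u2 < 1.0 / genotype.miwi_global_factor)
    read_by_pos = base.reads
    reads = [read_by_pos[i] for i in np.nonzero(keep)[0]]
    new_truth = truth.loc[keep].reset_index(drop=True)
    return SimulatedLibrary(label or genotype.kind, reads, new_truth, genotype)


def simulate_pair(
    cfg: ScenarioConfig, reference: Optional[Reference] = None
) -> tuple[Reference, SimulatedLibrary, SimulatedLibrary]:
    """Generate a paired wild-type/knockout design from one scenario.

    The knockout is a binomial thinning of the *same* base draw, so per-read
    truth links the two libraries and recovery bounds are exact.
    """
    reference = reference or make_reference(cfg)
    wt = simulate_library(cfg, reference, label="WT")
    ko = apply_genotype(wt, cfg.genotype, cfg, reference)
    return reference, wt, ko


def simulate_clip(cfg: ScenarioConfig, reference: Optional[Reference] = None) -> SimulatedLibrary:
    """Draw CLIP fragments from cluster positions.

    ``proportional`` mode reuses the piRNA abundance and hotspot models, so
    CLIP density tracks piRNA density; ``uniform`` mode picks clusters by
    length and positions uniformly. Fragment lengths are uniform in
    ``[min_len, max_len]`` (truncated at the cluster 3' end) and position 1
    is A with probability ``a1_prob`` exactly.
    """
    if not cfg.clip.enabled:
        raise ValueError("clip simulation disabled in this scenario")
    reference = reference or make_reference(cfg)
    rng = _rng(cfg.seed, "clip")
    clip = cfg.clip
    n = clip.n_reads
    order = reference.cluster_order
    lengths_by_cluster = {c: len(s) for c, s in reference.clusters.items()}
    if clip.density_source == "proportional":
        p = np.array([reference.abundance[c] for c in order])
    else:
        lens = np.array([lengths_by_cluster[c] for c in order], dtype=float)
        p = lens / lens.sum()
    counts = rng.multinomial(n, p)
    ids: list[str] = []
    seqs: list[str] = []
    rows: list[tuple] = []
    serial = 0
    for cluster, n_i in zip(order, counts):
        if n_i == 0:
            continue
        cseq = reference.clusters[cluster]
        L = lengths_by_cluster[cluster]
        if clip.density_source == "proportional":
            starts = _sample_cluster_starts(
                rng, reference, cluster, int(n_i), cfg.hotspots.background_fraction
            )
        else:
            starts = rng.integers(0, L - clip.min_len + 1, size=int(n_i))
        lens_i = rng.integers(clip.min_len, clip.max_len + 1, size=int(n_i))
        lens_i = np.minimum(lens_i, L - starts)
        raw = [cseq[s : s + l] for s, l in zip(starts, lens_i)]
        raw = _apply_first_nt_bias(rng, raw, "A", clip.a1_prob)
        for s, l, seq in zip(starts, lens_i, raw):
            rid = f"clip:{serial:07d}"
            serial += 1
            ids.append(rid)
            seqs.append(seq)
            rows.append((rid, CLUSTER_CATEGORY, cluster, int(s), int(l), "CLIP"))
    perm = rng.permutation(len(ids))
    truth = pd.DataFrame(
        rows, columns=["read_id", "category", "cluster", "true_start", "length", "length_class"]
    ).iloc[perm].reset_index(drop=True)
    reads = [SmallRNARead(ids[i], seqs[i], source="CLIP") for i in perm]
    return SimulatedLibrary("CLIP", reads, truth, GenotypeModel.wildtype())


# -- truth-table summaries used as test oracles -----------------------------

def cluster_truth_summary(truth: pd.DataFrame, window_nt: int) -> pd.DataFrame:
    """Per-cluster read counts and within-window start fraction ``w``."""
    cl = truth[truth["category"] == CLUSTER_CATEGORY].copy()
    cl["in_window"] = cl["true_start"] < window_nt
    grouped = cl.groupby("cluster", sort=True)
    out = grouped.size().rename("n_reads").to_frame()
    out["n_window"] = grouped["in_window"].sum().astype(int)
    out["window_fraction"] = out["n_window"] / out["n_reads"]
    return out.reset_index().rename(columns={"cluster": "cluster_id"})


def expected_full_length_fc(window_fraction: float, factor: float) -> float:
    """Closed-form WT/KO full-length fold change under 5'-window sparing.

    With a fraction ``w`` of a cluster's reads starting inside the spared
    window and the remainder thinned by ``1/factor``, the expected ratio of
    WT to KO cluster totals is ``1 / (w + (1 - w) / factor)``.
    """
    return 1.0 / (window_fraction + (1.0 - window_fraction) / factor)
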