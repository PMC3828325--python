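"""Synthetic two-platform microarray data with known ground truth.

The generator emulates the situation the rest of the package analyses:
two array platforms measuring the same RNA samples.  Genes are laid out
on one synthetic chromosome; each platform places 1–3 probes per gene at
random positions within the gene span, so cross-platform probe pairs
occur at a realistic spread of genomic distances.  Expression is driven
by a latent per-gene, per-sample transcript abundance:

* latent abundance ~ Normal(μ_g, 1) with μ_g ~ Uniform(4, 12) (log2-ish
  scale);
* a fixed subset of *signature genes* is shifted by ``effect_size_sd``
  in pathway-on samples (training cohort) and by a graded activation
  level drawn from Uniform(0, 1) × effect in the held-out test cohort,
  which mimics a tumor panel with heterogeneous pathway activity;
* each platform reports a continuous two-segment linear transform of
  the latent value (different slopes below/above a breakpoint, anchored
  so the signal at the breakpoint matches the platform's typical scale)
  plus two noise terms: independent probe noise with SD ``noise_sd``,
  and a *positional gradient* — a per-gene, per-sample random slope
  along the gene body (SD ``noise_sd``, length scale
  ``distance_decay_bp``), shared by both platforms because it is a
  property of the RNA sample (5'/3' degradation, isoform usage), and
  read out by each probe at its own position.

The positional gradient is what produces the hallmark behaviour of real
cross-platform comparisons: probe pairs that sit close together on the
genome read nearly the same gradient value and correlate strongly
across samples, pairs far apart diverge, and mutual best matches
out-correlate non-mutual ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import io as xio
from .probes import ProbeLocus, MappingTable, write_probe_bed, PAIR_COLUMNS
from .concordance import bin_by_distance

__all__ = ["SyntheticConfig", "FixtureBundle", "generate_probe_annotation",
           "generate_expression", "generate_fixture", "write_fixture"]


@dataclass(frozen=True)
class SyntheticConfig:
    """Full parameterization of the two-platform generator.

    Defaults mirror the scale of the real two-platform comparisons the
    package targets: ~2000 genes with 1–3 probes per platform, a signal
    breakpoint near 7 with a high-expression inter-platform slope close
    to 1.07, a 150-gene signature, 10+10 training samples and a
    16-sample heterogeneous test panel.
    """

    n_genes: int = 2000
    probes_per_gene_a: tuple = (1, 3)
    probes_per_gene_b: tuple = (1, 3)
    gene_span_bp: int = 5000
    gene_gap_bp: int = 1000
    probe_len_a: int = 400
    probe_len_b: int = 50
    breakpoint_latent: float = 7.0
    signal_at_breakpoint_a: float = 7.0
    signal_at_breakpoint_b: float = 6.7
    slope_low_a: float = 0.3
    slope_high_a: float = 1.0
    slope_low_b: float = 0.28
    slope_high_b: float = 0.93
    noise_sd: float = 0.2
    distance_decay_bp: float = 600.0
    n_signature_genes: int = 150
    effect_size_sd: float = 2.0
    n_control: int = 10
    n_pathway: int = 10
    n_test: int = 16
    seed: int = 0

    def __post_init__(self):
        for name in ("n_genes", "gene_span_bp", "n_signature_genes",
                     "n_control", "n_pathway", "n_test"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for name in ("slope_low_a", "slope_high_a", "slope_low_b",
                     "slope_high_b"):
            if getattr(self, name) <= 0:
                raise ValueError("platform slopes must be positive")
        if self.n_signature_genes > self.n_genes:
            raise ValueError("n_signature_genes cannot exceed n_genes")


@dataclass
class FixtureBundle:
    """Everything the generator knows about one synthetic study."""

    config: SyntheticConfig
    probes_a: list
    probes_b: list
    truth_mapping: MappingTable
    expr_train_a: pd.DataFrame
    expr_train_b: pd.DataFrame
    expr_test_a: pd.DataFrame
    expr_test_b: pd.DataFrame
    labels: pd.Series
    truth: dict = field(default_factory=dict)


def piecewise_transform(latent, *, breakpoint: float, slope_low: float,
                        slope_high: float, signal_at_breakpoint: float):
    """Continuous two-segment linear latent→signal map."""
    latent = np.asarray(latent, dtype=float)
    below = signal_at_breakpoint + slope_low * (latent - breakpoint)
    above = signal_at_breakpoint + slope_high * (latent - breakpoint)
    return np.where(latent <= breakpoint, below, above)


def _platform_transform(config: SyntheticConfig, platform: str):
    if platform == "A":
        return dict(breakpoint=config.breakpoint_latent,
                    slope_low=config.slope_low_a,
                    slope_high=config.slope_high_a,
                    signal_at_breakpoint=config.signal_at_breakpoint_a)
    return dict(breakpoint=config.breakpoint_latent,
                slope_low=config.slope_low_b,
                slope_high=config.slope_high_b,
                signal_at_breakpoint=config.signal_at_breakpoint_b)


def _place_probes(config: SyntheticConfig, rng: np.random.Generator,
                  platform: str):
    """Uniformly place probes inside each gene span for one platform."""
    lo, hi = (config.probes_per_gene_a if platform == "A"
              else config.probes_per_gene_b)
    plen = config.probe_len_a if platform == "A" else config.probe_len_b
    plen = min(plen, config.gene_span_bp)
    stride = config.gene_span_bp + config.gene_gap_bp
    counts = rng.integers(lo, hi + 1, size=config.n_genes)
    loci = []
    for g, k in enumerate(counts):
        gene_start = g * stride
        starts = np.sort(rng.integers(gene_start,
                                      gene_start + config.gene_span_bp - plen + 1,
                                      size=k))
        for j, start in enumerate(starts):
            loci.append(ProbeLocus(
                probe_id=f"{platform}_g{g:05d}_p{j}", platform_id=platform,
                chrom="chrS", start=int(start), end=int(start) + plen,
                strand="+", gene_id=f"gene{g:05d}"))
    return loci


def _intended_pairs(probes_a, probes_b) -> pd.DataFrame:
    """Ground-truth mutual best matches, by per-gene brute force.

    Independent of the production matcher: enumerates all same-gene
    pairs, applies the nearest rule (ties: smaller start, then probe id)
    in both directions, and keeps reciprocal pairs.
    """
    by_gene_b = {}
    for p in probes_b:
        by_gene_b.setdefault(p.gene_id, []).append(p)
    by_gene_a = {}
    for p in probes_a:
        by_gene_a.setdefault(p.gene_id, []).append(p)
    rows = []
    for gene, group_a in by_gene_a.items():
        group_b = by_gene_b.get(gene, [])
        if not group_b:
            continue
        key = lambda q, c: (abs(c.center - q.center), c.start, c.probe_id)
        best_b = {a.probe_id: min(group_b, key=lambda c: key(a, c))
                  for a in group_a}
        best_a = {b.probe_id: min(group_a, key=lambda c: key(b, c))
                  for b in group_b}
        for a in group_a:
            b = best_b[a.probe_id]
            if best_a[b.probe_id].probe_id == a.probe_id:
                rows.append((a.probe_id, b.probe_id, gene,
                             abs(a.center - b.center), True))
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS[:5])
    pairs["bin"] = bin_by_distance(pairs["distance_bp"].to_numpy()) if len(pairs) else pd.Series(dtype=object)
    return pairs.sort_values(["gene_id", "probe_a", "probe_b"],
                             kind="stable").reset_index(drop=True)


def generate_probe_annotation(config: SyntheticConfig,
                              rng: Optional[np.random.Generator] = None):
    """Probe loci for both platforms plus the ground-truth mutual pairing."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    probes_a = _place_probes(config, rng, "A")
    probes_b = _place_probes(config, rng, "B")
    truth = MappingTable(pairs=_intended_pairs(probes_a, probes_b),
                         platform_a_id="A", platform_b_id="B")
    return probes_a, probes_b, truth


def _probe_offsets(config: SyntheticConfig, probes) -> np.ndarray:
    """Signed probe-center offset from the gene midpoint, in bp."""
    stride = config.gene_span_bp + config.gene_gap_bp
    offsets = np.empty(len(probes))
    for i, p in enumerate(probes):
        g = int(p.gene_id.removeprefix("gene"))
        anchor = g * stride + config.gene_span_bp / 2
        offsets[i] = p.center - anchor
    return offsets


def generate_expression(config: SyntheticConfig, annotation,
                        rng: Optional[np.random.Generator] = None
                        ) -> FixtureBundle:
    """Expression matrices for both platforms, train and test cohorts."""
    if rng is None:
        rng = np.random.default_rng([config.seed, 1])
    probes_a, probes_b, truth_mapping = annotation
    n_train = config.n_control + config.n_pathway
    n_all = n_train + config.n_test

    mu = rng.uniform(4.0, 12.0, size=config.n_genes)
    signature_genes = np.sort(rng.choice(config.n_genes,
                                         size=config.n_signature_genes,
                                         replace=False))
    is_sig = np.zeros(config.n_genes, dtype=bool)
    is_sig[signature_genes] = True

    # per-sample pathway activation: 0/1 for the training cohort, graded
    # Uniform(0,1) for the heterogeneous test panel
    activation = np.concatenate([
        np.zeros(config.n_control),
        np.ones(config.n_pathway),
        rng.uniform(0.0, 1.0, size=config.n_test),
    ])
    latent = mu[:, None] + rng.standard_normal((config.n_genes, n_all))
    latent += config.effect_size_sd * np.outer(is_sig, activation)

    # positional gradient: per-gene per-sample, a property of the RNA
    # sample itself, so shared by both platforms
    gradient = config.noise_sd * rng.standard_normal((config.n_genes, n_all))

    sample_ids = ([f"ctrl_{i:02d}" for i in range(config.n_control)]
                  + [f"path_{i:02d}" for i in range(config.n_pathway)]
                  + [f"test_{i:02d}" for i in range(config.n_test)])
    labels = pd.Series(
        [0] * config.n_control + [1] * config.n_pathway,
        index=pd.Index(sample_ids[:n_train], name="sample_id"),
        name="label", dtype=int)

    matrices = {}
    for platform, probes in (("A", probes_a), ("B", probes_b)):
        gene_idx = np.array([int(p.gene_id.removeprefix("gene"))
                             for p in probes])
        signal = piecewise_transform(latent[gene_idx],
                                     **_platform_transform(config, platform))
        offsets = _probe_offsets(config, probes)
        signal = (signal
                  + gradient[gene_idx]
                  * (offsets[:, None] / config.distance_decay_bp)
                  + config.noise_sd * rng.standard_normal(signal.shape))
        frame = pd.DataFrame(signal, index=[p.probe_id for p in probes],
                             columns=sample_ids)
        matrices[platform] = frame

    # analytic per-pair correlation targets (local-slope approximation):
    # cov = s_a s_b + sigma^2 o_a o_b / delta^2, var_i = s_i^2 +
    # sigma^2 o_i^2 / delta^2 + sigma^2  (latent variance 1)
    targets = {}
    off_a = dict(zip((p.probe_id for p in probes_a),
                     _probe_offsets(config, probes_a)))
    off_b = dict(zip((p.probe_id for p in probes_b),
                     _probe_offsets(config, probes_b)))
    sigma2 = config.noise_sd ** 2
    delta2 = config.distance_decay_bp ** 2
    for row in truth_mapping.pairs.itertuples():
        g = int(row.gene_id.removeprefix("gene"))
        slope_a = (config.slope_low_a if mu[g] <= config.breakpoint_latent
                   else config.slope_high_a)
        slope_b = (config.slope_low_b if mu[g] <= config.breakpoint_latent
                   else config.slope_high_b)
        oa, ob = off_a[row.probe_a], off_b[row.probe_b]
        cov = slope_a * slope_b + sigma2 * oa * ob / delta2
        va = slope_a**2 + sigma2 * oa**2 / delta2 + sigma2
        vb = slope_b**2 + sigma2 * ob**2 / delta2 + sigma2
        targets[f"{row.probe_a}|{row.probe_b}"] = float(cov / np.sqrt(va * vb))

    truth = {
        "signature_genes": [f"gene{g:05d}" for g in signature_genes],
        "signature_probes_a": [p.probe_id for p in probes_a
                               if is_sig[int(p.gene_id.removeprefix("gene"))]],
        "signature_probes_b": [p.probe_id for p in probes_b
                               if is_sig[int(p.gene_id.removeprefix("gene"))]],
        "n_mutual_pairs": int(truth_mapping.pairs["mutual"].sum()),
        "test_activation": dict(zip(sample_ids[n_train:],
                                    map(float, activation[n_train:]))),
        "pair_correlation_targets": targets,
    }
    return FixtureBundle(
        config=config, probes_a=probes_a, probes_b=probes_b,
        truth_mapping=truth_mapping,
        expr_train_a=matrices["A"][sample_ids[:n_train]],
        expr_train_b=matrices["B"][sample_ids[:n_train]],
        expr_test_a=matrices["A"][sample_ids[n_train:]],
        expr_test_b=matrices["B"][sample_ids[n_train:]],
        labels=labels, truth=truth,
    )


def generate_fixture(config: SyntheticConfig = SyntheticConfig()) -> FixtureBundle:
    """One-call generator: annotation + expression from ``config.seed``."""
    rng = np.random.default_rng(config.seed)
    annotation = generate_probe_annotation(config, rng)
    return generate_expression(config, annotation, rng)


def write_fixture(bundle: FixtureBundle, out_dir) -> dict:
    """Write the bundle as plain-text files; returns a checksum manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_probe_bed(bundle.probes_a, out_dir / "probes_A.bed")
    write_probe_bed(bundle.probes_b, out_dir / "probes_B.bed")
    bundle.truth_mapping.write(out_dir / "truth_mapping.tsv")
    for name, frame in (("expr_train_A.tsv", bundle.expr_train_a),
                        ("expr_train_B.tsv", bundle.expr_train_b),
                        ("expr_test_A.tsv", bundle.expr_test_a),
                        ("expr_test_B.tsv", bundle.expr_test_b)):
        xio.write_expression(frame, out_dir / name)
    xio.write_labels(bundle.labels, out_dir / "labels.tsv")
    truth_doc = dict(bundle.truth)
    truth_doc["config"] = asdict(bundle.config)
    (out_dir / "truth.json").write_text(json.dumps(truth_doc, indent=1))
    manifest = {}
    for path in sorted(out_dir.iterdir()):
        if path.name == "manifest.json" or not path.is_file():
            continue
        manifest[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
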