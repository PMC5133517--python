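"""Synthetic cohorts with planted IBD structure for end-to-end pipeline testing.

The generator emulates the study design the pipeline targets: a cohort of
~105 unrelated individuals, a single chromosome carrying a background of
pairwise IBD segments of at least 1 cM at a chromosome-wide mean sharing rate
near 0.0029, and one causal locus where carriers of a shared ancestral
haplotype are all pairwise IBD and carry a trait shift.  The quantitative
trait is a blood-pressure-like phenotype (mm Hg) built from an intercept,
covariates (gender, age, smoking, three principal-component scores), the
carrier effect, and Gaussian noise; a treated subgroup is flagged so the
+5 mm Hg antihypertensive adjustment can be exercised downstream.

Background segments are an independent per-pair Poisson process: a Poisson
number of intervals whose lengths are the minimum detectable length plus an
exponential tail (defaults 1 cM + mean 0.47 cM, matching a realistic observed
mean of ~1.47 cM), placed uniformly along the chromosome.  The Poisson mean
is set so the expected covered fraction per pair equals ``background_rate``.
Physical and genetic coordinates are tied by a constant 1 cM/Mb, and the
emitted genetic map states exactly that, so fixtures are self-consistent
with the interpolation step.

A sequence region of ±1 Mb around the causal locus is populated with
variants for the variant-filter stage: a known number of multi-allelic,
monomorphic and high-missingness variants (which region QC must remove) and
clean variants, a chosen subset of which receive CADD scaled scores above 20
(the deleterious truth set).  Only a "sequenced" subset of the cohort gets
genotypes, mirroring sequence availability in real studies.

Everything is deterministic given ``SimConfig.seed``: the same seed yields
byte-identical fixture files.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ConfigError
from .ibd import GeneticMap, IbdMatrix, IbdSegment, build_matrix, write_ibd
from .variants import VariantRecord, write_vcf

BP_PER_CM = 1_000_000  # constant-rate physical<->genetic conversion

__all__ = ["SimConfig", "SimTruth", "simulate_cohort", "emit_fixtures"]


@dataclass(frozen=True)
class SimConfig:
    """Generator parameters; defaults reproduce the emulated study conditions."""

    n_individuals: int = 105
    chrom: str = "3"
    chrom_length_cM: float = 200.0
    n_markers: int = 2000
    background_rate: float = 0.0029
    min_seg_cM: float = 1.0
    seg_tail_mean_cM: float = 0.47
    qtl_position_cM: float = 100.0
    carrier_freq: float = 0.15
    qtl_effect: float = 14.0
    covariate_effects: tuple = (0.0, 0.0, 0.0, 18.2, 0.0, 0.0)
    intercept: float = 71.8
    noise_sd: float = 9.3
    treated_frac: float = 22 / 105
    n_region_variants: int = 200
    n_deleterious: int = 24
    sequenced_frac: float = 71 / 105
    seed: int = 0

    def validate(self) -> None:
        if self.n_individuals < 3:
            raise ConfigError("n_individuals", f"must be >= 3, got {self.n_individuals}")
        if not 0 <= self.background_rate < 1:
            raise ConfigError("background_rate", f"must be in [0, 1), got {self.background_rate}")
        if not 0 < self.carrier_freq < 1:
            raise ConfigError("carrier_freq", f"must be in (0, 1), got {self.carrier_freq}")
        if self.min_seg_cM < 1:
            raise ConfigError("min_seg_cM", f"detection floor is 1 cM, got {self.min_seg_cM}")
        if self.seg_tail_mean_cM < 0:
            raise ConfigError("seg_tail_mean_cM", "must be non-negative")
        if self.chrom_length_cM <= 2 * self.min_seg_cM:
            raise ConfigError("chrom_length_cM", "chromosome too short for the segment floor")
        if not 0 < self.qtl_position_cM < self.chrom_length_cM:
            raise ConfigError("qtl_position_cM", "must lie strictly inside the chromosome")
        if self.n_markers < 1:
            raise ConfigError("n_markers", "need at least one marker")
        if self.noise_sd <= 0:
            raise ConfigError("noise_sd", "must be positive")
        if not 0 <= self.treated_frac <= 1:
            raise ConfigError("treated_frac", "must be in [0, 1]")
        if not 0 < self.sequenced_frac <= 1:
            raise ConfigError("sequenced_frac", "must be in (0, 1]")
        if len(self.covariate_effects) < 3:
            raise ConfigError("covariate_effects", "need >= 3 effects (gender, age, smoking)")
        n_clean = self.n_region_variants - self._n_planted_failures()
        if self.n_deleterious > n_clean:
            raise ConfigError(
                "n_deleterious",
                f"only {n_clean} clean variants available for {self.n_deleterious} deleterious",
            )

    def _n_planted_failures(self) -> int:
        n = self.n_region_variants
        return round(0.05 * n) + round(0.10 * n) + round(0.10 * n)

    @property
    def n_pcs(self) -> int:
        return len(self.covariate_effects) - 3

    @classmethod
    def from_yaml(cls, path) -> "SimConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "covariate_effects" in raw:
            raw["covariate_effects"] = tuple(raw["covariate_effects"])
        return cls(**raw)

    def with_seed(self, seed: int) -> "SimConfig":
        return replace(self, seed=seed)


@dataclass
class SimTruth:
    """Everything the generator knows about a simulated cohort."""

    config: SimConfig
    carrier_flags: pd.Series
    causal_interval_cM: tuple[float, float]
    background_segments: list[IbdSegment]
    causal_segments: list[IbdSegment]
    phenotypes: pd.DataFrame
    marker_positions_bp: np.ndarray
    vcf_samples: list[str]
    variants: list[VariantRecord] = field(default_factory=list)
    cadd: pd.DataFrame | None = None
    deleterious_keys: list[tuple] = field(default_factory=list)

    @property
    def planted_segments(self) -> list[IbdSegment]:
        """All planted segments (background + causal), sorted by (pair, start)."""
        segs = self.background_segments + self.causal_segments
        return sorted(segs, key=lambda s: (s.pair(), s.start_bp, s.end_bp))

    @property
    def causal_interval_bp(self) -> tuple[int, int]:
        lo, hi = self.causal_interval_cM
        return (int(round(lo * BP_PER_CM)), int(round(hi * BP_PER_CM)))

    def ids(self) -> list[str]:
        return list(self.phenotypes["id"])

    def ibd_matrix(self) -> IbdMatrix:
        return build_matrix(
            self.planted_segments, self.marker_positions_bp, self.ids(), chrom=self.config.chrom
        )

    def genetic_map(self) -> GeneticMap:
        n_mb = int(np.ceil(self.config.chrom_length_cM)) + 1
        pos = np.arange(n_mb + 1, dtype=float) * BP_PER_CM
        return GeneticMap(self.config.chrom, pos, pos / BP_PER_CM)


def _segment(cfg, id1, id2, start_cM, end_cM, hap1, hap2, lod) -> IbdSegment:
    a, b = (id1, id2) if id1 <= id2 else (id2, id1)
    return IbdSegment(
        id1=a, hap1=int(hap1), id2=b, hap2=int(hap2), chrom=cfg.chrom,
        start_bp=int(round(start_cM * BP_PER_CM)),
        end_bp=int(round(end_cM * BP_PER_CM)),
        lod=float(np.round(lod, 2)),
    )


def _draw_lengths(rng, cfg, size):
    return cfg.min_seg_cM + rng.exponential(cfg.seg_tail_mean_cM, size)


def _simulate_phenotypes(rng, cfg, ids, carrier):
    gender = rng.random(cfg.n_individuals) < 0.41
    age = rng.normal(56.6, 15.5, cfg.n_individuals)
    smoking = rng.random(cfg.n_individuals) < 0.24
    pcs = rng.normal(0.0, 0.05, (cfg.n_individuals, cfg.n_pcs))
    treated = rng.random(cfg.n_individuals) < cfg.treated_frac
    noise = rng.normal(0.0, cfg.noise_sd, cfg.n_individuals)

    effects = np.asarray(cfg.covariate_effects, dtype=float)
    X = np.column_stack([gender.astype(float), age, smoking.astype(float), pcs])
    dbp = cfg.intercept + X @ effects + cfg.qtl_effect * carrier.astype(float) + noise

    table = pd.DataFrame(
        {
            "id": ids,
            "dbp": dbp,
            "treated": treated,
            "gender": gender,
            "age": age,
            "smoking": smoking,
        }
    )
    for k in range(cfg.n_pcs):
        table[f"pc{k + 1}"] = pcs[:, k]
    return table


def _simulate_background(rng, cfg, ids):
    """Per-pair Poisson number of uniformly placed shifted-exponential segments."""
    pairs = list(combinations(ids, 2))
    mean_len = cfg.min_seg_cM + cfg.seg_tail_mean_cM
    lam = cfg.background_rate * cfg.chrom_length_cM / mean_len
    counts = rng.poisson(lam, len(pairs))
    total = int(counts.sum())
    lengths = np.minimum(_draw_lengths(rng, cfg, total), cfg.chrom_length_cM)
    starts = rng.uniform(0.0, cfg.chrom_length_cM - lengths)
    haps = rng.integers(1, 3, (total, 2))
    lods = rng.uniform(3.0, 12.0, total)
    segments = []
    k = 0
    for (a, b), c in zip(pairs, counts):
        for _ in range(c):
            segments.append(
                _segment(cfg, a, b, starts[k], starts[k] + lengths[k], *haps[k], lods[k])
            )
            k += 1
    return segments


def _simulate_causal(rng, cfg, carrier_ids, marker_cM):
    """One QTL-covering segment per carrier pair; returns (segments, interval).

    Every causal segment covers both the QTL position and the marker nearest
    to it, so carrier-carrier sharing is observable at that marker by
    construction whatever the marker density.
    """
    cc_pairs = list(combinations(carrier_ids, 2))
    if not cc_pairs:
        return [], (cfg.qtl_position_cM, cfg.qtl_position_cM)
    q = cfg.qtl_position_cM
    nearest = float(marker_cM[np.argmin(np.abs(marker_cM - q))])
    eps = 0.02 * cfg.min_seg_cM
    lo_t, hi_t = min(q, nearest) - eps, max(q, nearest) + eps
    n_cc = len(cc_pairs)
    lengths = np.maximum(_draw_lengths(rng, cfg, n_cc), (hi_t - lo_t) + eps)
    starts = rng.uniform(hi_t - lengths, np.full(n_cc, lo_t))
    ends = starts + lengths
    shift = np.maximum(0.0, -starts)
    starts, ends = starts + shift, ends + shift
    over = np.maximum(0.0, ends - cfg.chrom_length_cM)
    starts, ends = np.maximum(starts - over, 0.0), ends - over
    haps = rng.integers(1, 3, (len(cc_pairs), 2))
    lods = rng.uniform(3.0, 12.0, len(cc_pairs))
    segments = [
        _segment(cfg, a, b, s, e, *h, lod)
        for (a, b), s, e, h, lod in zip(cc_pairs, starts, ends, haps, lods)
    ]
    return segments, (float(starts.min()), float(ends.max()))


def _random_alleles(rng, n_alts):
    bases = np.array(list("ACGT"))
    picks = rng.permutation(4)[: n_alts + 1]
    return bases[picks[0]], tuple(bases[picks[1:]])


def _simulate_variants(rng, cfg, ids):
    """Region variants around the QTL with planted QC failures and CADD scores."""
    n_seq = max(2, int(round(cfg.sequenced_frac * cfg.n_individuals)))
    seq_ids = sorted(str(s) for s in rng.choice(ids, size=n_seq, replace=False))

    qtl_bp = int(round(cfg.qtl_position_cM * BP_PER_CM))
    span = 2_000_000
    lo = max(1, qtl_bp - span // 2)
    positions = np.sort(rng.choice(np.arange(lo, lo + span), cfg.n_region_variants, replace=False))

    n = cfg.n_region_variants
    n_multi, n_mono, n_miss = round(0.05 * n), round(0.10 * n), round(0.10 * n)
    kinds = np.array(
        ["multi"] * n_multi + ["mono"] * n_mono + ["highmiss"] * n_miss
        + ["clean"] * (n - n_multi - n_mono - n_miss)
    )
    rng.shuffle(kinds)

    max_missing = int(np.floor(0.15 * n_seq))
    variants = []
    for pos, kind in zip(positions, kinds):
        ref, alts = _random_alleles(rng, 2 if kind == "multi" else 1)
        if kind == "mono":
            geno = np.zeros(n_seq)
        else:
            f = rng.uniform(0.05, 0.5)
            geno = rng.binomial(2, f, n_seq).astype(float)
        if kind == "highmiss":
            n_missing = int(rng.integers(max_missing + 1, max(max_missing + 2, n_seq // 2)))
            geno[rng.choice(n_seq, n_missing, replace=False)] = np.nan
        elif kind == "clean":
            n_missing = int(rng.integers(0, max_missing + 1))
            if n_missing:
                geno[rng.choice(n_seq, n_missing, replace=False)] = np.nan
        if kind == "clean":
            observed = ~np.isnan(geno)
            if np.nansum(geno) == 0 or np.nansum(geno) == 2 * observed.sum():
                geno[np.flatnonzero(observed)[0]] = 1.0  # keep clean variants polymorphic
        variants.append(
            VariantRecord(chrom=cfg.chrom, pos=int(pos), ref=str(ref), alts=alts, genotypes=geno)
        )

    clean_idx = np.flatnonzero(kinds == "clean")
    deleterious_idx = set(rng.choice(clean_idx, cfg.n_deleterious, replace=False).tolist())
    scores = np.where(
        np.isin(np.arange(n), list(deleterious_idx)),
        rng.uniform(20.5, 45.0, n),
        rng.uniform(0.1, 19.9, n),
    )
    cadd = pd.DataFrame(
        {
            "chrom": [v.chrom for v in variants],
            "pos": [v.pos for v in variants],
            "ref": [v.ref for v in variants],
            "alt": [",".join(v.alts) for v in variants],
            "cadd_scaled": np.round(scores, 3),
        }
    )
    deleterious_keys = [variants[i].key for i in sorted(deleterious_idx)]
    return seq_ids, variants, cadd, deleterious_keys


def simulate_cohort(config: SimConfig) -> SimTruth:
    """Draw a full synthetic cohort; deterministic given ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    width = max(3, len(str(config.n_individuals)))
    ids = [f"I{k:0{width}d}" for k in range(1, config.n_individuals + 1)]

    spacing = config.chrom_length_cM / config.n_markers
    marker_cM = (np.arange(config.n_markers) + 0.5) * spacing
    marker_bp = np.round(marker_cM * BP_PER_CM).astype(np.int64)

    carrier = rng.random(config.n_individuals) < config.carrier_freq
    phenotypes = _simulate_phenotypes(rng, config, ids, carrier)
    background = _simulate_background(rng, config, ids)
    carrier_ids = [i for i, c in zip(ids, carrier) if c]
    causal, interval = _simulate_causal(rng, config, carrier_ids, marker_cM)
    seq_ids, variants, cadd, deleterious_keys = _simulate_variants(rng, config, ids)

    return SimTruth(
        config=config,
        carrier_flags=pd.Series(carrier, index=ids, name="carrier"),
        causal_interval_cM=interval,
        background_segments=background,
        causal_segments=causal,
        phenotypes=phenotypes,
        marker_positions_bp=marker_bp,
        vcf_samples=seq_ids,
        variants=variants,
        cadd=cadd,
        deleterious_keys=deleterious_keys,
    )


def emit_fixtures(truth: SimTruth, out_dir) -> dict[str, str]:
    """Write the on-disk fixture set; returns a name -> path manifest.

    Files: Refined-IBD-dialect ``segments.ibd``, HapMap-style
    ``genetic_map.txt``, ``phenotypes.tsv``, ``markers.tsv``, ``region.vcf``
    and ``cadd.tsv``.  All of them round-trip losslessly through the package
    parsers, and identical seeds give byte-identical files.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    manifest = {
        "ibd": str(out / "segments.ibd"),
        "map": str(out / "genetic_map.txt"),
        "phenotypes": str(out / "phenotypes.tsv"),
        "markers": str(out / "markers.tsv"),
        "vcf": str(out / "region.vcf"),
        "cadd": str(out / "cadd.tsv"),
    }
    write_ibd(truth.planted_segments, manifest["ibd"])
    truth.genetic_map().write(manifest["map"])

    pheno = truth.phenotypes.copy()
    for col in ("treated", "gender", "smoking"):
        pheno[col] = pheno[col].astype(int)
    pheno.to_csv(manifest["phenotypes"], sep="\t", index=False, float_format="%.6f")

    with open(manifest["markers"], "w") as fh:
        fh.write("marker\tposition_bp\n")
        for i, pos in enumerate(truth.marker_positions_bp):
            fh.write(f"m{i:05d}\t{pos}\n")

    write_vcf(truth.vcf_samples, truth.variants, manifest["vcf"], contig=truth.config.chrom)
    truth.cadd.to_csv(manifest["cadd"], sep="\t", index=False, float_format="%.3f")
    return manifest
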