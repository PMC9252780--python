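"""Dosage genotype I/O, variant/sample quality control and relatedness pruning.

Genotypes are additive alternate-allele dosages in [0, 2]; missing entries
are encoded as NaN and are only imputed downstream (at the PCA stage), so QC
statistics here are computed on observed data.  Variant filters follow the
inclusive thresholds MAF >= 1% and imputation info score >= 0.6; variants and
samples with more than 2% missing data are excluded.  Cryptic relatedness is
handled by pruning one member of every pair above the third-degree kinship
cutoff (0.0884).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .regions import GenomicInterval

logger = logging.getLogger(__name__)

DEFAULT_MAF_MIN = 0.01
DEFAULT_INFO_MIN = 0.6
DEFAULT_MISSING_MAX = 0.02
DEFAULT_KINSHIP_THRESHOLD = 0.0884


@dataclass(frozen=True)
class VariantRecord:
    variant_id: str
    chrom: str
    pos: int
    ref: str
    alt: str
    maf: float
    info: float
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.maf <= 0.5:
            raise ValueError(f"{self.variant_id}: maf {self.maf} outside [0, 0.5]")
        if not 0.0 <= self.info <= 1.0:
            raise ValueError(f"{self.variant_id}: info {self.info} outside [0, 1]")
        if not 0.0 <= self.missing_rate <= 1.0:
            raise ValueError(
                f"{self.variant_id}: missing_rate {self.missing_rate} outside [0, 1]"
            )


@dataclass(frozen=True)
class KinshipPair:
    id1: str
    id2: str
    coefficient: float

    def __post_init__(self) -> None:
        if self.id1 == self.id2:
            raise ValueError(f"kinship pair with identical ids: {self.id1}")
        if self.coefficient < 0:
            raise ValueError("kinship coefficient must be >= 0")


@dataclass
class DosageMatrix:
    """samples x variants additive dosage matrix; NaN marks missing."""

    sample_ids: list[str]
    variants: list[VariantRecord]
    dosages: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.sample_ids), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.variants)} variants"
            )
        observed = self.dosages[~np.isnan(self.dosages)]
        if observed.size and (observed.min() < 0 or observed.max() > 2):
            raise ValueError("dosages outside [0, 2]")

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    def variant_ids(self) -> list[str]:
        return [v.variant_id for v in self.variants]

    def take_variants(self, idx: np.ndarray) -> "DosageMatrix":
        return DosageMatrix(
            sample_ids=list(self.sample_ids),
            variants=[self.variants[i] for i in idx],
            dosages=self.dosages[:, idx],
        )

    def take_samples(self, idx: np.ndarray) -> "DosageMatrix":
        return DosageMatrix(
            sample_ids=[self.sample_ids[i] for i in idx],
            variants=list(self.variants),
            dosages=self.dosages[idx, :],
        )

    def recompute_stats(self) -> "DosageMatrix":
        """Recompute per-variant MAF and missing rate from the current samples."""
        new_variants = []
        for j, v in enumerate(self.variants):
            col = self.dosages[:, j]
            mask = np.isnan(col)
            miss = float(mask.mean()) if col.size else 0.0
            obs = col[~mask]
            if obs.size:
                af = float(obs.mean() / 2.0)
                maf = min(af, 1.0 - af)
            else:
                maf = 0.0
            new_variants.append(replace(v, maf=maf, missing_rate=miss))
        return DosageMatrix(list(self.sample_ids), new_variants, self.dosages)

    # -- TSV dialect ------------------------------------------------------
    def to_tsv(self, dosage_path: str | Path, meta_path: str | Path) -> None:
        """Write the dosage matrix and the per-variant metadata sidecar."""
        df = pd.DataFrame(self.dosages, columns=self.variant_ids())
        df.insert(0, "sample_id", self.sample_ids)
        df.to_csv(dosage_path, sep="\t", index=False, na_rep="NA",
                  float_format="%.6g")
        meta = pd.DataFrame(
            [
                (v.variant_id, v.chrom, v.pos, v.ref, v.alt, v.maf, v.info,
                 v.missing_rate)
                for v in self.variants
            ],
            columns=["variant_id", "chrom", "pos", "ref", "alt", "maf", "info",
                     "missing_rate"],
        )
        meta.to_csv(meta_path, sep="\t", index=False, float_format="%.10g")


def _read_dosage_tsv(
    path: Path, region: GenomicInterval | None, meta_path: Path | None
) -> DosageMatrix:
    df = pd.read_csv(path, sep="\t", na_values=["NA"])
    if df.columns[0] != "sample_id":
        raise ValueError(f"{path}: first column must be sample_id")
    sample_ids = df["sample_id"].astype(str).tolist()
    dosages = df.iloc[:, 1:].to_numpy(dtype=float)
    var_ids = list(df.columns[1:])

    meta: dict[str, dict] = {}
    if meta_path is not None:
        mdf = pd.read_csv(meta_path, sep="\t")
        meta = {str(r.variant_id): r for r in mdf.itertuples(index=False)}

    variants: list[VariantRecord] = []
    keep: list[int] = []
    for j, vid in enumerate(var_ids):
        m = meta.get(vid)
        chrom = str(m.chrom) if m is not None else (region.chrom if region else ".")
        pos = int(m.pos) if m is not None else 0
        if region is not None and m is not None and not region.contains(chrom, pos):
            continue
        col = dosages[:, j]
        mask = np.isnan(col)
        obs = col[~mask]
        af = float(obs.mean() / 2.0) if obs.size else 0.0
        variants.append(VariantRecord(
            variant_id=vid,
            chrom=chrom,
            pos=pos,
            ref=str(getattr(m, "ref", "A")) if m is not None else "A",
            alt=str(getattr(m, "alt", "B")) if m is not None else "B",
            maf=float(getattr(m, "maf", min(af, 1 - af))) if m is not None
                else min(af, 1 - af),
            info=float(getattr(m, "info", 1.0)) if m is not None else 1.0,
            missing_rate=float(mask.mean()),
        ))
        keep.append(j)
    return DosageMatrix(sample_ids, variants, dosages[:, keep])


def _read_dosage_vcf(
    path: Path,
    region: GenomicInterval,
    dosage_field: str,
    info_field: str,
) -> DosageMatrix:
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    variants: list[VariantRecord] = []
    cols: list[np.ndarray] = []
    indexed = any(Path(str(path) + ext).exists() for ext in (".tbi", ".csi"))
    if indexed:
        region_iter = vcf(f"{region.chrom}:{region.start}-{region.end}")
    else:
        # no index: full scan with interval membership
        region_iter = (v for v in vcf if region.contains(v.CHROM, v.POS))
    for rec in region_iter:
        if not region.contains(rec.CHROM, rec.POS):
            continue
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        ds = rec.format(dosage_field)
        if ds is None:
            raise ValueError(f"variant {vid}: missing FORMAT field {dosage_field}")
        col = np.asarray(ds, dtype=float).reshape(-1)
        col = np.where((col < 0) | (col > 2), np.nan, col)
        mask = np.isnan(col)
        obs = col[~mask]
        af = float(obs.mean() / 2.0) if obs.size else 0.0
        info = rec.INFO.get(info_field)
        if info is None:
            info = rec.INFO.get("R2", 1.0)
        variants.append(VariantRecord(
            variant_id=vid, chrom=rec.CHROM, pos=rec.POS, ref=rec.REF,
            alt=rec.ALT[0] if rec.ALT else ".", maf=min(af, 1.0 - af),
            info=float(info), missing_rate=float(mask.mean()),
        ))
        cols.append(col)
    dosages = (np.column_stack(cols) if cols
               else np.empty((len(sample_ids), 0)))
    return DosageMatrix(sample_ids, variants, dosages)


def read_dosages(
    path: str | Path,
    region: GenomicInterval | None = None,
    format: str | None = None,
    dosage_field: str = "DS",
    info_field: str = "INFO",
    meta_path: str | Path | None = None,
) -> DosageMatrix:
    """Read a region's dosages from a VCF (FORMAT ``DS``) or the TSV dialect.

    For VCF input the imputation info score is taken from the configured INFO
    key (fallback ``R2``, then 1.0); for TSV input metadata comes from the
    sidecar ``meta_path`` when given, otherwise MAF/missingness are computed
    from the extracted samples.  A region with no variants yields an empty
    matrix with all samples, not an error.
    """
    path = Path(path)
    if format is None:
        name = path.name.lower()
        format = "vcf" if (".vcf" in name or name.endswith(".bcf")) else "tsv"
    if format == "vcf":
        if region is None:
            raise ValueError("a region is required for VCF extraction")
        return _read_dosage_vcf(path, region, dosage_field, info_field)
    if format == "tsv":
        return _read_dosage_tsv(
            path, region, Path(meta_path) if meta_path else None
        )
    raise ValueError(f"unknown genotype format: {format!r}")


def filter_variants(
    dm: DosageMatrix,
    maf_min: float = DEFAULT_MAF_MIN,
    info_min: float = DEFAULT_INFO_MIN,
    missing_max: float = DEFAULT_MISSING_MAX,
) -> DosageMatrix:
    """Keep variants with maf >= maf_min, info >= info_min and
    missing_rate <= missing_max (thresholds inclusive; exclusion on
    missingness is strictly greater-than)."""
    keep = np.array(
        [
            (v.info >= info_min) and (v.maf >= maf_min)
            and (v.missing_rate <= missing_max)
            for v in dm.variants
        ],
        dtype=bool,
    )
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_variants: removed %d of %d variants", n_drop,
                    dm.n_variants)
    return dm.take_variants(np.flatnonzero(keep))


def filter_samples_missingness(
    dm: DosageMatrix, missing_max: float = DEFAULT_MISSING_MAX
) -> DosageMatrix:
    """Remove samples whose fraction of missing dosages exceeds missing_max."""
    if dm.n_variants == 0:
        return dm
    frac = np.isnan(dm.dosages).mean(axis=1)
    keep = frac <= missing_max
    n_drop = int((~keep).sum())
    if n_drop:
        logger.info("filter_samples_missingness: removed %d of %d samples",
                    n_drop, dm.n_samples)
    return dm.take_samples(np.flatnonzero(keep))


def read_kinship_pairs(path: str | Path) -> list[KinshipPair]:
    """Read a KING-style kinship TSV with columns id1, id2, kinship."""
    df = pd.read_csv(path, sep="\t")
    required = {"id1", "id2", "kinship"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: kinship TSV must have columns {sorted(required)}")
    return [
        KinshipPair(str(r.id1), str(r.id2), float(r.kinship))
        for r in df.itertuples(index=False)
    ]


def prune_related(
    pairs: list[KinshipPair],
    samples: set[str],
    threshold: float = DEFAULT_KINSHIP_THRESHOLD,
    seed: int = 0,
) -> set[str]:
    """Prune related samples by degree-peeling the kinship graph.

    Edges are pairs with coefficient >= threshold.  The highest-degree node
    is removed repeatedly (ties broken by a seeded random choice) until no
    edges remain; the retained set never contains both members of any
    above-threshold pair.  Deterministic given ``seed``.
    """
    if threshold < 0:
        raise ValueError("threshold must be >= 0")
    rng = np.random.default_rng(seed)
    adj: dict[str, set[str]] = {}
    for p in pairs:
        if p.coefficient < threshold:
            continue
        if p.id1 not in samples or p.id2 not in samples:
            logger.warning("kinship pair (%s, %s) references unknown sample; "
                           "ignored", p.id1, p.id2)
            continue
        adj.setdefault(p.id1, set()).add(p.id2)
        adj.setdefault(p.id2, set()).add(p.id1)

    removed: set[str] = set()
    while True:
        degrees = {node: len(nbrs) for node, nbrs in adj.items() if nbrs}
        if not degrees:
            break
        max_deg = max(degrees.values())
        candidates = sorted(n for n, d in degrees.items() if d == max_deg)
        victim = candidates[rng.integers(len(candidates))]
        removed.add(victim)
        for nbr in adj.pop(victim):
            adj[nbr].discard(victim)
    return set(samples) - removed
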