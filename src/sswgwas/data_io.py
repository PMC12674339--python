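"""File formats and run configuration.

Pedigree and phenotype CSV/TSV, genotype VCF (GT only), results TSVs and a
YAML-backed run configuration. Everything downstream consumes the in-memory
types; no other module touches files.
"""
from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .genotypes import AlleleFrequencies, GenotypeMatrix, QcReport, chrom_sort_key
from .kinship import MarkerWeights
from .mme import PhenotypeTable, VarianceComponents
from .pedigree import MISSING_PARENT_CODES, Pedigree
from .wssgwas import RegionSet, SnpEffects, WindowResult, manhattan_table

log = logging.getLogger(__name__)

#: contig labels treated as mitochondrial (after stripping a "chr" prefix)
_MITO_LABELS = frozenset({"mt", "m", "mito", "mitochondrion"})


@dataclass
class RunConfig:
    """Thresholds and knobs for a full analysis run."""

    maf_min: float = 0.05
    call_rate_min: float = 0.90
    hwe_alpha: float = 1e-6
    mendel_conflict_max: float = 0.01
    ld_r2_max: float = 1.0
    alpha_blend: float = 0.95
    window_size: int = 30
    region_threshold_pct: float = 0.5
    n_weight_iterations: int = 2
    outlier_sd: float = 3.0
    seed: int = 0
    trait_floors: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("maf_min", "call_rate_min", "mendel_conflict_max",
                     "ld_r2_max", "alpha_blend"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if not 0.0 < self.hwe_alpha < 1.0:
            raise ValueError("hwe_alpha must lie in (0, 1)")
        if self.window_size < 1:
            raise ValueError("window_size must be >= 1")
        if self.n_weight_iterations < 1:
            raise ValueError("n_weight_iterations must be >= 1")

    def rng(self) -> np.random.Generator:
        """Root generator; all randomness must flow from here."""
        return np.random.default_rng(self.seed)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))


def _read_table(path: str | Path) -> pd.DataFrame:
    sep = "\t" if str(path).endswith((".tsv", ".tab", ".txt")) else ","
    return pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)


def read_pedigree(
    path: str | Path,
    id_columns: Sequence[str] = ("animal", "sire", "dam"),
) -> Pedigree:
    """Read an animal/sire/dam table; unknown parents coded 0, empty or NA."""
    df = _read_table(path)
    missing = [c for c in id_columns if c not in df.columns]
    if missing:
        raise ValueError(f"pedigree file lacks columns: {missing}")
    a, s, d = id_columns
    return Pedigree.from_records(zip(df[a], df[s], df[d]))


def write_pedigree(ped: Pedigree, path: str | Path) -> None:
    pd.DataFrame({
        "animal": ped.ids,
        "sire": ["0" if p < 0 else ped.ids[p] for p in ped.sire],
        "dam": ["0" if p < 0 else ped.ids[p] for p in ped.dam],
    }).to_csv(path, index=False)


def _contig_excluded(chrom: str) -> bool:
    c = str(chrom).lower()
    if "scaffold" in c:
        return True
    core = c[3:] if c.startswith("chr") else c
    return core in _MITO_LABELS


def read_genotypes_vcf(path: str | Path) -> GenotypeMatrix:
    """Read biallelic GT records into an ALT-dosage matrix.

    Multi-allelic records are skipped (counted), records on scaffold or
    mitochondrial contigs are dropped, and the SNP map is sorted by
    (chromosome, position).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if not samples:
        raise ValueError(f"VCF {path} declares no samples")
    rows = []
    meta = []
    n_multi = 0
    n_contig = 0
    for var in vcf:
        if len(var.ALT) != 1:
            n_multi += 1
            continue
        if _contig_excluded(var.CHROM):
            n_contig += 1
            continue
        # gt_types: 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        gt = np.asarray(var.gt_types)
        dos = np.choose(gt, [0.0, 1.0, 0.0, 2.0])
        rows.append((dos, gt == 2))
        meta.append((str(var.CHROM), int(var.POS),
                     var.ID or f"{var.CHROM}_{var.POS}"))
    vcf.close()
    if n_multi:
        log.info("skipped %d multi-allelic records", n_multi)
    if n_contig:
        log.info("excluded %d records on scaffold/mitochondrial contigs", n_contig)
    if not meta:
        raise ValueError(f"no usable biallelic records in {path}")
    order = sorted(range(len(meta)),
                   key=lambda i: (chrom_sort_key(meta[i][0]), meta[i][1]))
    dosages = np.stack([rows[i][0] for i in order], axis=1)
    mask = np.stack([rows[i][1] for i in order], axis=1)
    snp_map = pd.DataFrame(
        [meta[i] for i in order], columns=["chrom", "pos", "id"]
    )
    return GenotypeMatrix(dosages, mask, snp_map, samples)


def write_genotypes_vcf(g: GenotypeMatrix, path: str | Path) -> None:
    """Write the dosage matrix as a minimal GT-only VCF."""
    gtmap = {0.0: "0/0", 1.0: "0/1", 2.0: "1/1"}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in pd.unique(g.snp_map["chrom"]):
            fh.write(f"##contig=<ID={chrom}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(g.animal_ids) + "\n")
        for j in range(g.n_snps):
            chrom, pos, sid = (g.snp_map["chrom"][j], g.snp_map["pos"][j],
                               g.snp_map["id"][j])
            calls = [
                "./." if g.missing_mask[i, j] else gtmap[float(g.dosages[i, j])]
                for i in range(g.n_animals)
            ]
            fh.write(f"{chrom}\t{pos}\t{sid}\tA\tG\t.\t.\t.\tGT\t"
                     + "\t".join(calls) + "\n")


def read_phenotypes(
    path: str | Path,
    trait: str,
    fixed_factors: Sequence[str] = (),
    covariates: Sequence[str] = (),
    animal_column: str = "animal",
    pedigree: Pedigree | None = None,
) -> PhenotypeTable:
    """Read a phenotype CSV; rows with any missing model term are dropped."""
    df = _read_table(path)
    if trait not in df.columns:
        raise ValueError(f"trait column {trait!r} absent from {path}")
    needed = [animal_column, trait, *fixed_factors, *covariates]
    missing_cols = [c for c in needed if c not in df.columns]
    if missing_cols:
        raise ValueError(f"phenotype file lacks columns: {missing_cols}")
    ok = np.ones(len(df), dtype=bool)
    for c in needed:
        ok &= df[c].str.strip().str.lower().map(
            lambda s: s not in {"", "na", "nan", "none", "."}
        ).to_numpy()
    n_drop = int((~ok).sum())
    if n_drop:
        log.info("dropped %d phenotype rows with missing model terms", n_drop)
    df = df[ok]
    if df.empty:
        raise ValueError("all phenotype rows were dropped")
    if pedigree is not None:
        for a in df[animal_column]:
            if a not in pedigree:
                raise ValueError(f"phenotyped animal {a!r} absent from pedigree")
    return PhenotypeTable(
        animal=df[animal_column].to_numpy(dtype=object),
        y=df[trait].astype(float).to_numpy(),
        factors={f: df[f].to_numpy(dtype=object) for f in fixed_factors},
        covariates={c: df[c].astype(float).to_numpy() for c in covariates},
        trait=trait,
    )


def write_phenotypes(ph: PhenotypeTable, path: str | Path) -> None:
    df = pd.DataFrame({"animal": ph.animal, ph.trait: ph.y})
    for k, v in ph.factors.items():
        df[k] = v
    for k, v in ph.covariates.items():
        df[k] = v
    df.to_csv(path, index=False)


def write_dosage_matrix(g: GenotypeMatrix, path: str | Path, map_path: str | Path) -> None:
    """Plain TSV dosage matrix (rows = animals) plus a SNP map TSV."""
    df = pd.DataFrame(
        np.where(g.missing_mask, np.nan, g.dosages),
        columns=g.snp_map["id"], index=pd.Index(g.animal_ids, name="animal"),
    )
    df.to_csv(path, sep="\t", na_rep="NA")
    g.snp_map.to_csv(map_path, sep="\t", index=False)


def read_dosage_matrix(path: str | Path, map_path: str | Path) -> GenotypeMatrix:
    df = pd.read_csv(path, sep="\t", index_col="animal")
    snp_map = pd.read_csv(map_path, sep="\t", dtype={"chrom": str, "pos": int, "id": str})
    dos = df.to_numpy(dtype=float)
    mask = ~np.isfinite(dos)
    return GenotypeMatrix(np.nan_to_num(dos), mask, snp_map,
                          [str(a) for a in df.index])


def _windows_frame(windows: Sequence[WindowResult]) -> pd.DataFrame:
    return pd.DataFrame(
        [{
            "window_id": w.window_id, "chrom": w.chrom,
            "start_bp": w.start_bp, "end_bp": w.end_bp,
            "first_snp": w.first_snp, "last_snp": w.last_snp,
            "n_snps": w.n_snps, "pct_var": w.pct_var,
        } for w in windows],
        columns=["window_id", "chrom", "start_bp", "end_bp",
                 "first_snp", "last_snp", "n_snps", "pct_var"],
    )


def write_results(
    out_dir: str | Path,
    snp_map: pd.DataFrame,
    effects: SnpEffects,
    weights: MarkerWeights,
    windows: Sequence[WindowResult],
    regions: RegionSet,
    vc: VarianceComponents | None = None,
    qc_reports: Sequence[QcReport] = (),
) -> dict[str, Path]:
    """Write per-SNP effects, window percentages, regions and Manhattan TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    eff = pd.DataFrame({
        "snp_id": snp_map["id"], "chrom": snp_map["chrom"], "pos": snp_map["pos"],
        "u_hat": effects.u_hat, "weight": weights.d,
    })
    paths["snp_effects"] = out / "snp_effects.tsv"
    eff.to_csv(paths["snp_effects"], sep="\t", index=False)

    paths["windows"] = out / "windows.tsv"
    _windows_frame(windows).to_csv(paths["windows"], sep="\t", index=False)

    paths["regions"] = out / "regions.tsv"
    _windows_frame(regions.windows).to_csv(paths["regions"], sep="\t", index=False)

    paths["manhattan"] = out / "manhattan.tsv"
    manhattan_table(list(windows)).to_csv(paths["manhattan"], sep="\t", index=False)

    if vc is not None:
        paths["varcomp"] = out / "varcomp.tsv"
        pd.DataFrame([{
            "sigma2_u": vc.sigma2_u, "sigma2_e": vc.sigma2_e, "h2": vc.h2,
            "se_h2": vc.se_h2, "converged": vc.converged,
            "n_iter": vc.n_iter, "loglik": vc.loglik,
        }]).to_csv(paths["varcomp"], sep="\t", index=False)

    if qc_reports:
        paths["qc_report"] = out / "qc_report.tsv"
        pd.DataFrame([{
            "criterion": r.criterion, "n_removed": r.n_removed,
            "removed": ";".join(r.removed_snps + r.removed_animals),
            "n_remaining_snps": r.n_remaining_snps,
            "n_remaining_animals": r.n_remaining_animals,
        } for r in qc_reports]).to_csv(paths["qc_report"], sep="\t", index=False)
    return paths


def read_snp_effects(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"chrom": str})


def read_windows(path: str | Path) -> list[WindowResult]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return [
        WindowResult(
            window_id=int(r.window_id), chrom=str(r.chrom),
            start_bp=int(r.start_bp), end_bp=int(r.end_bp),
            first_snp=str(r.first_snp), last_snp=str(r.last_snp),
            n_snps=int(r.n_snps), pct_var=float(r.pct_var),
        )
        for r in df.itertuples()
    ]
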