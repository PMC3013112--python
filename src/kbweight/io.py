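"""Readers, writers, run configuration and the synthetic-genome generator.

Formats handled
---------------
- PLINK ``.assoc``-style association tables (whitespace- or tab-delimited;
  needs SNP and P or CHISQ).
- Per-SNP annotation TSV: snp_id, chrom, pos, feature_class, gene,
  conservation, selection, mirna_site (empty string = missing).
- Gene models: refFlat-like TSV (gene, chrom, strand, txStart, txEnd;
  1-based inclusive) or BED (0-based half-open, converted on read).
- Pathways as GMT; PPI as a two-column TSV edge list; LD proxies as a
  four-column TSV (local_snp, proxy_snp, r2, proxy_score).

All coordinates are handled internally as 1-based inclusive.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .annotation import FeatureClass, SnpAnnotation

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "read_assoc",
    "read_annotation",
    "read_gene_models",
    "read_gmt",
    "read_ppi",
    "read_ld_proxies",
    "read_gene_list",
    "generate_fixture_genome",
    "write_report",
    "write_trace",
]

_CONFIG_FIELDS = {
    "assoc", "annotation", "genes", "pathways", "ppi", "ld", "seeds",
    "cons_threshold", "sel_threshold", "r2_threshold", "cutoff",
    "top_n", "q", "max_iter", "rng_seed", "base_scores",
}


@dataclasses.dataclass
class RunConfig:
    """Resolved run configuration (flat key-value YAML file + CLI overrides)."""

    assoc: str | None = None
    annotation: str | None = None
    genes: str | None = None
    pathways: str | None = None
    ppi: str | None = None
    ld: str | None = None
    seeds: str | None = None
    cons_threshold: float = 0.8
    sel_threshold: float = 2.0
    r2_threshold: float = 0.9
    cutoff: int = 4
    top_n: int = 20
    q: float = 0.05
    max_iter: int = 20
    rng_seed: int = 0
    base_scores: dict | None = None

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - _CONFIG_FIELDS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if not 0.0 <= self.cons_threshold <= 1.0:
            raise ValueError("cons_threshold outside [0, 1]")
        if not 0.0 <= self.r2_threshold <= 1.0:
            raise ValueError("r2_threshold outside [0, 1]")
        if self.cutoff < 0 or self.top_n < 1 or self.max_iter < 1:
            raise ValueError("cutoff/top_n/max_iter out of range")
        if not 0.0 < self.q < 1.0:
            raise ValueError("q outside (0, 1)")

    def snapshot(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(dataclasses.asdict(self)))


def read_assoc(path: str | Path) -> pd.DataFrame:
    """Parse a PLINK ``.assoc``-style table into (snp_id, chrom, pos, p, chisq).

    Requires SNP plus P and/or CHISQ columns; either statistic is derived
    from the other through the chi-square(1 df) tail.  Rows with
    non-numeric P/CHISQ are dropped (count logged).
    """
    df = pd.read_csv(path, sep=r"\s+")
    df.columns = [c.upper() for c in df.columns]
    if "SNP" not in df.columns:
        raise ValueError(f"{path}: missing required column SNP")
    if "P" not in df.columns and "CHISQ" not in df.columns:
        raise ValueError(f"{path}: missing required column P or CHISQ")
    for col in ("P", "CHISQ"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    value_cols = [c for c in ("P", "CHISQ") if c in df.columns]
    before = len(df)
    df = df.dropna(subset=value_cols, how="all")
    dropped = before - len(df)
    if dropped:
        logger.info("%s: dropped %d row(s) with non-numeric statistics", path, dropped)
    out = pd.DataFrame({"snp_id": df["SNP"].astype(str)})
    out["chrom"] = df["CHR"].astype(str).to_numpy() if "CHR" in df.columns else ""
    out["pos"] = df["BP"].to_numpy() if "BP" in df.columns else 0
    if "P" in df.columns:
        p = df["P"].to_numpy(dtype=float)
        chisq = df["CHISQ"].to_numpy(dtype=float) if "CHISQ" in df.columns else stats.chi2.isf(p, 1)
        missing = np.isnan(chisq)
        if missing.any():
            chisq[missing] = stats.chi2.isf(p[missing], 1)
    else:
        chisq = df["CHISQ"].to_numpy(dtype=float)
        p = stats.chi2.sf(chisq, 1)
    missing_p = np.isnan(p)
    if missing_p.any():
        p = p.copy()
        p[missing_p] = stats.chi2.sf(chisq[missing_p], 1)
    out["p"] = p
    out["chisq"] = chisq
    return out.reset_index(drop=True)


_BOOL = {"1": True, "true": True, "0": False, "false": False, "": False}


def read_annotation(path: str | Path) -> list[SnpAnnotation]:
    """Read the per-SNP annotation TSV (empty string = missing value)."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for row in df.itertuples(index=False):
        records.append(
            SnpAnnotation(
                snp_id=row.snp_id,
                chrom=row.chrom,
                pos=int(row.pos),
                feature_class=FeatureClass(row.feature_class),
                gene=row.gene or None,
                conservation=float(row.conservation) if row.conservation else None,
                selection=float(row.selection) if row.selection else None,
                mirna_site=_BOOL[str(row.mirna_site).strip().lower()],
            )
        )
    return records


def write_annotation(records: list[SnpAnnotation], path: str | Path) -> None:
    rows = []
    for a in records:
        rows.append({
            "snp_id": a.snp_id,
            "chrom": a.chrom,
            "pos": a.pos,
            "feature_class": a.feature_class.value,
            "gene": a.gene or "",
            "conservation": "" if a.conservation is None else repr(a.conservation),
            "selection": "" if a.selection is None else repr(a.selection),
            "mirna_site": "1" if a.mirna_site else "0",
        })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """refFlat-like TSV or BED gene models -> 1-based inclusive bounds."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        df = pd.read_csv(
            path, sep="\t", header=None,
            names=["chrom", "start", "end", "gene", "score", "strand"],
            usecols=range(6),
        )
        return pd.DataFrame({
            "gene": df["gene"],
            "chrom": df["chrom"].astype(str),
            "strand": df["strand"],
            "txStart": df["start"] + 1,  # BED is 0-based half-open
            "txEnd": df["end"],
        })
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "chrom", "strand", "txStart", "txEnd"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: gene model file needs columns {sorted(required)}")
    df["chrom"] = df["chrom"].astype(str)
    return df


def read_gmt(path: str | Path) -> dict[str, set[str]]:
    """GMT pathway file: name <tab> description <tab> gene1 <tab> ..."""
    pathways: dict[str, set[str]] = {}
    for line in Path(path).read_text().splitlines():
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}: malformed GMT line {line[:60]!r}")
        pathways[parts[0]] = {g for g in parts[2:] if g}
    return pathways


def read_ppi(path: str | Path) -> list[tuple[str, str]]:
    """Two-column TSV edge list (header optional, detected by 'gene')."""
    edges = []
    for i, line in enumerate(Path(path).read_text().splitlines()):
        if not line.strip():
            continue
        u, v = line.split("\t")[:2]
        if i == 0 and u.lower() in ("gene_a", "gene1", "protein_a"):
            continue
        edges.append((u, v))
    return edges


def read_ld_proxies(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"local_snp", "proxy_snp", "r2", "proxy_score"}
    if not required <= set(df.columns):
        raise ValueError(f"{path}: LD proxy file needs columns {sorted(required)}")
    return df


def read_gene_list(path: str | Path) -> frozenset[str]:
    return frozenset(
        g.strip() for g in Path(path).read_text().splitlines() if g.strip()
    )


def generate_fixture_genome(
    out_dir: str | Path,
    n_snps: int = 2000,
    n_genes: int = 100,
    n_pathways: int = 20,
    planted_signals: int = 3,
    n_cases: int = 1000,
    n_controls: int = 1000,
    rng_seed: int = 0,
) -> dict[str, Path]:
    """Write a mutually consistent synthetic input bundle to ``out_dir``.

    Generates gene models on a toy genome, SNPs with annotation features,
    pathway and PPI resources, an LD-proxy table and a PLINK-style
    association file in which ``planted_signals`` SNPs placed inside
    candidate-extendable genes carry both strong functional features and
    real association signal (non-central chi-square statistics).
    Byte-identical across runs for a fixed ``rng_seed``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(rng_seed)

    genes = [f"G{i:04d}" for i in range(n_genes)]
    gene_len = 20_000
    gap = 30_000
    rows = []
    for i, g in enumerate(genes):
        chrom = str(1 + i % 4)
        start = 10_000 + (i // 4) * (gene_len + gap)
        rows.append((g, chrom, "+" if i % 2 == 0 else "-", start, start + gene_len - 1))
    gene_models = pd.DataFrame(rows, columns=["gene", "chrom", "strand", "txStart", "txEnd"])
    genes_path = out / "genes.tsv"
    gene_models.to_csv(genes_path, sep="\t", index=False)

    # pathways: random gene blocks; pathway 0 always contains the signal genes
    pathways_lines = []
    signal_genes = genes[:planted_signals]
    for j in range(n_pathways):
        if j == 0:
            members = signal_genes + list(
                rng.choice(genes[planted_signals:], size=5, replace=False)
            )
        else:
            size = int(rng.integers(3, 11))  # scaled to the toy gene universe
            members = list(rng.choice(genes, size=size, replace=False))
        pathways_lines.append(
            "\t".join([f"PW{j:03d}", f"synthetic pathway {j}"] + members)
        )
    gmt_path = out / "pathways.gmt"
    gmt_path.write_text("\n".join(pathways_lines) + "\n")

    # PPI: sparse random graph (mean degree ~2, like curated interactomes)
    # plus one edge tying each signal gene to a shared partner
    ppi_rows = ["gene_a\tgene_b"]
    for _ in range(n_genes):
        u, v = rng.choice(genes, size=2, replace=False)
        ppi_rows.append(f"{u}\t{v}")
    partner = genes[n_genes // 2]
    for g in signal_genes:
        ppi_rows.append(f"{g}\t{partner}")
    ppi_path = out / "ppi.tsv"
    ppi_path.write_text("\n".join(ppi_rows) + "\n")

    # SNPs: uniformly over gene bodies / flanks / intergenic space
    feature_choices = np.array([
        FeatureClass.INTRON.value, FeatureClass.SYNONYMOUS.value,
        FeatureClass.NONSYNONYMOUS.value, FeatureClass.UTR.value,
        FeatureClass.UPSTREAM.value, FeatureClass.DOWNSTREAM.value,
    ])
    feature_probs = np.array([0.55, 0.1, 0.05, 0.1, 0.12, 0.08])
    ann_rows = []
    assoc_rows = []
    in_gene = rng.random(n_snps) < 0.5
    signal_idx = set(range(planted_signals))
    for i in range(n_snps):
        snp = f"rs{i:06d}"
        if i in signal_idx:
            gm = gene_models.iloc[i]
            gene, chrom = gm.gene, gm.chrom
            pos = int(rng.integers(gm.txStart, gm.txEnd + 1))
            feature = FeatureClass.NONSYNONYMOUS.value
            cons = float(np.round(rng.uniform(0.85, 1.0), 3))
            sel, mirna = "", "0"
            ncp = rng.uniform(20, 30)
            chisq = float(stats.ncx2.rvs(1, ncp, random_state=rng))
        else:
            if in_gene[i]:
                gm = gene_models.iloc[int(rng.integers(n_genes))]
                gene, chrom = gm.gene, gm.chrom
                pos = int(rng.integers(gm.txStart, gm.txEnd + 1))
                feature = str(rng.choice(feature_choices, p=feature_probs))
            else:
                gene = ""
                chrom = str(int(rng.integers(1, 5)))
                pos = int(rng.integers(1, 3_000_000))
                feature = FeatureClass.INTERGENIC.value
            cons = float(np.round(rng.uniform(0, 1), 3)) if rng.random() < 0.6 else ""
            sel = float(np.round(rng.normal(0, 1), 3)) if rng.random() < 0.3 else ""
            mirna = "1" if rng.random() < 0.03 else "0"
            chisq = float(stats.chi2.rvs(1, random_state=rng))
        p = float(stats.chi2.sf(chisq, 1))
        ann_rows.append({
            "snp_id": snp, "chrom": chrom, "pos": pos, "feature_class": feature,
            "gene": gene, "conservation": cons, "selection": sel, "mirna_site": mirna,
        })
        assoc_rows.append({
            "CHR": chrom, "SNP": snp, "BP": pos,
            "CHISQ": f"{chisq:.6g}", "P": f"{p:.6g}",
        })
    ann_path = out / "annotation.tsv"
    pd.DataFrame(ann_rows).to_csv(ann_path, sep="\t", index=False)
    assoc_path = out / "assoc.tsv"
    pd.DataFrame(assoc_rows).to_csv(assoc_path, sep=" ", index=False)

    # LD proxies: a few high-r2 proxies carrying higher scores
    ld_rows = []
    proxy_targets = rng.choice(n_snps, size=max(n_snps // 100, 1), replace=False)
    for k, tgt in enumerate(sorted(proxy_targets)):
        ld_rows.append({
            "local_snp": f"rs{tgt:06d}",
            "proxy_snp": f"hap{k:04d}",
            "r2": float(np.round(rng.uniform(0.85, 1.0), 3)),
            "proxy_score": int(rng.integers(0, 7)),
        })
    ld_path = out / "ld_proxies.tsv"
    pd.DataFrame(ld_rows).to_csv(ld_path, sep="\t", index=False)

    seeds_path = out / "seeds.txt"
    seeds_path.write_text("\n".join(signal_genes) + "\n")

    return {
        "assoc": assoc_path,
        "annotation": ann_path,
        "genes": genes_path,
        "pathways": gmt_path,
        "ppi": ppi_path,
        "ld": ld_path,
        "seeds": seeds_path,
    }


def write_report(
    table: pd.DataFrame,
    candidates,
    pathways: dict[str, set[str]],
    ppi_edges: list[tuple[str, str]],
    out_dir: str | Path,
    highlight_threshold: float = 5e-4,
) -> dict[str, Path]:
    """Write the ranked SNP report and the highlighted-gene PPI edge list.

    ``table`` is the per-SNP output of an iteration (snp_id, p, score,
    clue_set, weight, weighted_p, bh_flag).  Provenance columns record the
    candidate gene and how it entered the extended set.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    ann = table.sort_values(["weighted_p", "snp_id"]).reset_index(drop=True)
    snp_gene = ann.get("gene")
    genes = snp_gene if snp_gene is not None else pd.Series([""] * len(ann))
    provenance, via_pathway = [], []
    gene_pw = {}
    for name, members in pathways.items():
        for g in members:
            gene_pw.setdefault(g, name)
    for g in genes:
        if candidates is not None and g and g in candidates.extended:
            how = candidates.provenance.get(g, "")
            provenance.append(how)
            via_pathway.append(gene_pw.get(g, "") if how == "pathway" else "")
        else:
            provenance.append("")
            via_pathway.append("")
    ann["candidate_provenance"] = provenance
    ann["via_pathway"] = via_pathway
    report_path = out / "snp_report.tsv"
    ann.to_csv(report_path, sep="\t", index=False)

    highlighted = set(
        genes[(ann["weighted_p"] <= highlight_threshold) & (genes != "")]
    ) if len(ann) else set()
    sub_edges = [
        (u, v) for u, v in ppi_edges
        if u in highlighted or v in highlighted
    ]
    edges_path = out / "highlighted_ppi_edges.tsv"
    with open(edges_path, "w") as fh:
        fh.write("gene_a\tgene_b\n")
        for u, v in sub_edges:
            fh.write(f"{u}\t{v}\n")
    return {"report": report_path, "ppi_edges": edges_path}


def write_trace(trace, path: str | Path) -> None:
    """JSON-lines log: one WeightSolution per iteration."""
    with open(path, "w") as fh:
        for i, sol in enumerate(trace):
            fh.write(json.dumps({"iteration": i + 1, **sol.as_dict()}) + "\n")
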