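"""VCF and TSV entry points (pysam-backed).

Biallelic SNP records only; multiallelic or indel records are rejected with
their position. Coordinates are 1-based in VCF and 0-based internally — the
boundary lives in this module only. Conventions: PL is the usual scaled
integer phred log-likelihood (0 for the best genotype), DS is written with 3
decimals, GP with 5 and normalized, so DS = GP(1) + 2 GP(2) holds within
rounding on every written record.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pysam

from .impute import ImputedDosages
from .reads import MISSING, CalledGenotypes, GenotypeLikelihoods
from .simulate import DiploidGenotypes, GWASWeights, HaplotypePanel

__all__ = [
    "write_panel_vcf",
    "read_panel_vcf",
    "write_reads_vcf",
    "read_gl_vcf",
    "read_calls_vcf",
    "write_dosage_vcf",
    "read_dosage_vcf",
    "write_weights_tsv",
    "read_weights_tsv",
]

CONTIG = "1"


def _header(n_samples: int, prefix: str, formats, infos=(), contig_len=536_870_912):
    h = pysam.VariantHeader()
    h.add_line(f"##contig=<ID={CONTIG},length={contig_len}>")
    for line in formats:
        h.add_line(line)
    for line in infos:
        h.add_line(line)
    for i in range(n_samples):
        h.add_sample(f"{prefix}{i:04d}")
    return h


def _check_biallelic_snp(rec) -> None:
    if len(rec.alleles) != 2 or any(len(a) != 1 for a in rec.alleles):
        raise ValueError(
            f"record at position {rec.pos} is not a biallelic SNP: {rec.alleles}"
        )


def write_panel_vcf(panel: HaplotypePanel, path: str) -> None:
    """Phased GT export of a reference panel (requires an even haplotype count)."""
    if panel.n_haplotypes % 2:
        raise ValueError("panel VCF export needs an even number of haplotypes")
    n_samples = panel.n_haplotypes // 2
    h = _header(n_samples, "ref", ['##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">'])
    with pysam.VariantFile(path, "w", header=h) as vf:
        for m in range(panel.n_sites):
            rec = vf.new_record(
                contig=CONTIG,
                start=int(panel.positions[m]) - 1,
                alleles=(str(panel.ref[m]), str(panel.alt[m])),
                id=str(panel.site_ids[m]),
            )
            for s in range(n_samples):
                rec.samples[s]["GT"] = (
                    int(panel.alleles[2 * s, m]),
                    int(panel.alleles[2 * s + 1, m]),
                )
                rec.samples[s].phased = True
            vf.write(rec)


def read_panel_vcf(path: str) -> HaplotypePanel:
    positions, ids, ref, alt, cols = [], [], [], [], []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            _check_biallelic_snp(rec)
            positions.append(rec.pos)
            ids.append(rec.id)
            ref.append(rec.alleles[0])
            alt.append(rec.alleles[1])
            col = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                col.extend(gt)
            cols.append(col)
    alleles = np.array(cols, dtype=np.uint8).T
    return HaplotypePanel(
        positions=np.array(positions),
        alleles=alleles,
        site_ids=np.array(ids, dtype=object),
        ref=np.array(ref, dtype=object),
        alt=np.array(alt, dtype=object),
    )


def _pl_from_loggl(log_gl: np.ndarray) -> np.ndarray:
    pl = -10.0 / np.log(10.0) * (log_gl - log_gl.max(axis=-1, keepdims=True))
    return np.rint(np.clip(pl, 0, 255)).astype(int)


def write_reads_vcf(
    gl: GenotypeLikelihoods,
    path: str,
    calls: CalledGenotypes | None = None,
    panel: HaplotypePanel | None = None,
) -> None:
    """Sequencing evidence as GT (hard calls, ./." when missing), PL and DP."""
    N, M, _ = gl.log_gl.shape
    h = _header(
        N,
        "smp",
        [
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
            '##FORMAT=<ID=PL,Number=G,Type=Integer,Description="Phred-scaled genotype likelihoods">',
            '##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">',
        ],
    )
    pl = _pl_from_loggl(gl.log_gl)
    gt_map = {0: (0, 0), 1: (0, 1), 2: (1, 1), MISSING: (None, None)}
    with pysam.VariantFile(path, "w", header=h) as vf:
        for m in range(M):
            ref = str(panel.ref[m]) if panel is not None else "A"
            alt = str(panel.alt[m]) if panel is not None else "C"
            rec = vf.new_record(
                contig=CONTIG,
                start=int(gl.positions[m]) - 1,
                alleles=(ref, alt),
                id=str(gl.site_ids[m]),
            )
            for n in range(N):
                g = int(calls.calls[n, m]) if calls is not None else MISSING
                rec.samples[n]["GT"] = gt_map[g]
                rec.samples[n]["PL"] = tuple(int(x) for x in pl[n, m])
                rec.samples[n]["DP"] = int(gl.depth[n, m])
            vf.write(rec)


def read_gl_vcf(path: str) -> GenotypeLikelihoods:
    """Load PL-field likelihoods; a VCF without PL is a format error."""
    pls, depths, positions, ids = [], [], [], []
    with pysam.VariantFile(path) as vf:
        if "PL" not in vf.header.formats:
            raise ValueError("VCF lacks the PL FORMAT field required for GL-mode input")
        samples = list(vf.header.samples)
        for rec in vf:
            _check_biallelic_snp(rec)
            positions.append(rec.pos)
            ids.append(rec.id)
            pls.append([rec.samples[s]["PL"] for s in samples])
            depths.append(
                [rec.samples[s].get("DP", 0) or 0 for s in samples]
            )
    pl = np.array(pls, dtype=float)  # (M, N, 3)
    log_gl = -pl * np.log(10.0) / 10.0
    return GenotypeLikelihoods(
        log_gl=np.transpose(log_gl, (1, 0, 2)),
        depth=np.array(depths, dtype=np.int64).T,
        positions=np.array(positions),
        site_ids=np.array(ids, dtype=object),
    )


def read_calls_vcf(path: str) -> CalledGenotypes:
    calls, positions, ids = [], [], []
    with pysam.VariantFile(path) as vf:
        samples = list(vf.header.samples)
        for rec in vf:
            _check_biallelic_snp(rec)
            positions.append(rec.pos)
            ids.append(rec.id)
            row = []
            for s in samples:
                gt = rec.samples[s]["GT"]
                row.append(MISSING if gt is None or gt[0] is None else sum(gt))
            calls.append(row)
    return CalledGenotypes(
        calls=np.array(calls, dtype=np.int8).T,
        positions=np.array(positions),
        site_ids=np.array(ids, dtype=object),
    )


def write_dosage_vcf(
    dosages: ImputedDosages, path: str, panel: HaplotypePanel | None = None
) -> None:
    """Imputation output: DS and GP per sample, INFO R2 per site."""
    N, M, _ = dosages.gp.shape
    h = _header(
        N,
        "smp",
        [
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Posterior alt-allele dosage">',
            '##FORMAT=<ID=GP,Number=3,Type=Float,Description="Posterior genotype probabilities">',
        ],
        ['##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation INFO score">'],
    )
    ds = dosages.dosage
    with pysam.VariantFile(path, "w", header=h) as vf:
        for m in range(M):
            ref = str(panel.ref[m]) if panel is not None else "A"
            alt = str(panel.alt[m]) if panel is not None else "C"
            rec = vf.new_record(
                contig=CONTIG,
                start=int(dosages.positions[m]) - 1,
                alleles=(ref, alt),
                id=str(dosages.site_ids[m]),
            )
            rec.info["R2"] = round(float(dosages.info[m]), 5)
            for n in range(N):
                gp = dosages.gp[n, m]
                gp = np.round(gp / gp.sum(), 5)
                rec.samples[n]["DS"] = round(float(ds[n, m]), 3)
                rec.samples[n]["GP"] = tuple(float(x) for x in gp)
            vf.write(rec)


def read_dosage_vcf(path: str) -> ImputedDosages:
    gps, infos, positions, ids = [], [], [], []
    with pysam.VariantFile(path) as vf:
        if "GP" not in vf.header.formats:
            raise ValueError("VCF lacks the GP FORMAT field required for dosage input")
        samples = list(vf.header.samples)
        for rec in vf:
            _check_biallelic_snp(rec)
            positions.append(rec.pos)
            ids.append(rec.id)
            infos.append(rec.info.get("R2", float("nan")))
            gps.append([rec.samples[s]["GP"] for s in samples])
    gp = np.transpose(np.array(gps, dtype=float), (1, 0, 2))
    gp = gp / gp.sum(axis=-1, keepdims=True)
    return ImputedDosages(
        gp=gp,
        positions=np.array(positions),
        site_ids=np.array(ids, dtype=object),
        info=np.array(infos, dtype=float),
    )


def write_weights_tsv(weights: GWASWeights, path: str, truth: bool = False) -> None:
    """Weight table TSV: site_id, effect_allele (ref/alt marker), weight, p_value.

    ``truth=True`` additionally writes the simulation ground-truth columns.
    """
    df = weights.to_frame()
    if not truth:
        df = df[["site_id", "effect_allele", "weight", "p_value"]]
    df.to_csv(path, sep="\t", index=False)


def read_weights_tsv(path: str) -> GWASWeights:
    df = pd.read_csv(path, sep="\t")
    n = len(df)
    return GWASWeights(
        site_id=df["site_id"].to_numpy(dtype=object),
        effect_allele=df["effect_allele"].to_numpy(dtype=object),
        weight=df["weight"].to_numpy(dtype=float),
        p_value=df["p_value"].to_numpy(dtype=float),
        is_causal=(
            df["is_causal"].to_numpy(dtype=bool)
            if "is_causal" in df
            else np.zeros(n, dtype=bool)
        ),
        true_beta=(
            df["true_beta"].to_numpy(dtype=float)
            if "true_beta" in df
            else np.zeros(n)
        ),
    )
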