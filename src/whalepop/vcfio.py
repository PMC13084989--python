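"""VCF v4.2 and sidecar-table I/O for genotype datasets.

Writing is done with a small deterministic text emitter (a fixed seed must
yield byte-identical files); reading goes through cyvcf2.  Truth metadata
(ancestral alleles, pedigree, tracts) travels in plain-TSV sidecar files next
to the VCF, and scaffold lengths in a two-column TSV.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .simulate import GenotypeDataset

__all__ = ["write_vcf", "read_vcf", "read_scaffold_lengths"]

_HEADER = """\
##fileformat=VCFv4.2
##source=whalepop
##INFO=<ID=MQ,Number=1,Type=Float,Description="RMS mapping quality">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Combined depth across samples">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Read depth">
##FORMAT=<ID=GQ,Number=1,Type=Integer,Description="Genotype quality">
"""


def write_vcf(dataset: GenotypeDataset, path: str,
              depth_model: tuple[float, float] | None = None,
              gq_model: tuple[float, float] | None = None,
              seed: int = 0) -> None:
    """Write a dataset as VCF v4.2 plus truth/scaffold sidecar TSVs.

    ``depth_model`` is (mean DP, negative-binomial overdispersion) and
    ``gq_model`` (mean GQ, sd); when given they redraw the per-genotype
    metadata with ``seed``, otherwise the dataset's stored DP/GQ are written.
    A zero-site dataset produces a header-only VCF.
    """
    dp, gq = dataset.dp, dataset.gq
    if depth_model is not None or gq_model is not None:
        rng = np.random.default_rng(seed)
        if depth_model is not None:
            m, k = depth_model
            if k <= 0:
                dp = rng.poisson(m, size=dp.shape).astype(np.int32)
            else:
                dp = rng.negative_binomial(k, k / (k + m),
                                           size=dp.shape).astype(np.int32)
        if gq_model is not None:
            m, s = gq_model
            gq = np.clip(np.rint(rng.normal(m, s, size=gq.shape)),
                         0, 99).astype(np.int32)

    sep = "|" if dataset.phased else "/"
    lines = [_HEADER]
    for sc, length in zip(dataset.scaffold_ids, dataset.scaffold_lengths):
        lines.append(f"##contig=<ID={sc},length={int(length)}>\n")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(dataset.sample_ids) + "\n")

    h = dataset.haplotypes
    for s in range(dataset.n_sites):
        sc = dataset.scaffold_ids[dataset.site_scaffold[s]]
        info = f"MQ={dataset.mq[s]:g};DP={int(dp[s].sum())}"
        cells = []
        for i in range(dataset.n_samples):
            a, b = h[s, 2 * i], h[s, 2 * i + 1]
            gt = f"{'.' if a < 0 else a}{sep}{'.' if b < 0 else b}"
            cells.append(f"{gt}:{dp[s, i]}:{gq[s, i]}")
        lines.append(
            f"{sc}\t{dataset.positions[s]}\t.\t{dataset.ref[s]}\t"
            f"{dataset.alt[s]}\t.\tPASS\t{info}\tGT:DP:GQ\t"
            + "\t".join(cells) + "\n")
    with open(path, "w") as fh:
        fh.writelines(lines)

    _write_sidecars(dataset, path)


def _write_sidecars(dataset, path):
    pd.DataFrame({"scaffold": dataset.scaffold_ids,
                  "length": dataset.scaffold_lengths}).to_csv(
        path + ".scaffolds.tsv", sep="\t", index=False)
    anc_char = np.where(dataset.ancestral == 1, dataset.alt,
                        np.where(dataset.ancestral == 0, dataset.ref, "."))
    pd.DataFrame({
        "scaffold": [dataset.scaffold_ids[i] for i in dataset.site_scaffold],
        "pos": dataset.positions,
        "ancestral": anc_char,
    }).to_csv(path + ".truth.tsv", sep="\t", index=False)
    pd.DataFrame({"sample": dataset.sample_ids,
                  "population": dataset.sample_population}).to_csv(
        path + ".samples.tsv", sep="\t", index=False)
    tracts = dataset.truth.get("ibd_tracts")
    if tracts is not None:
        tracts.to_csv(path + ".tracts.tsv", sep="\t", index=False)


def read_scaffold_lengths(path: str) -> dict[str, int]:
    df = pd.read_csv(path, sep="\t")
    return dict(zip(df.iloc[:, 0].astype(str), df.iloc[:, 1].astype(int)))


def read_vcf(path: str) -> GenotypeDataset:
    """Read a VCF (with optional whalepop sidecars) into a GenotypeDataset.

    Restores the genotype matrix bit-exactly for files written by
    :func:`write_vcf`.  Multiallelic records are collapsed to their first ALT
    allele with other alleles set missing (downstream stages that require
    biallelic sites re-filter explicitly).
    """
    from cyvcf2 import VCF

    vcf = VCF(path)
    samples = list(vcf.samples)
    n = len(samples)

    scaff_order: list[str] = []
    scaff_len: dict[str, int] = {}
    for line in vcf.raw_header.splitlines():
        if line.startswith("##contig"):
            body = line.split("<", 1)[1].rstrip(">")
            fields = dict(kv.split("=", 1) for kv in body.split(","))
            scaff_order.append(fields["ID"])
            scaff_len[fields["ID"]] = int(fields.get("length", 0))

    chroms, positions, ref, alt, mq = [], [], [], [], []
    hap_rows, dp_rows, gq_rows = [], [], []
    phased = True
    for v in vcf:
        chroms.append(v.CHROM)
        positions.append(v.POS)
        ref.append(v.REF[0] if v.REF else "N")
        alt.append(v.ALT[0][0] if v.ALT else ".")
        try:
            mq.append(float(v.INFO.get("MQ", np.nan)))
        except (TypeError, ValueError):
            mq.append(np.nan)
        row = np.empty(2 * n, dtype=np.int8)
        for i, g in enumerate(v.genotypes):
            a, b = g[0], g[1] if len(g) > 2 else -1
            row[2 * i] = -1 if a < 0 else (1 if a >= 1 else 0)
            row[2 * i + 1] = -1 if b < 0 else (1 if b >= 1 else 0)
            # alleles beyond the first ALT are treated as missing
            if a > 1:
                row[2 * i] = -1
            if b > 1:
                row[2 * i + 1] = -1
            if len(g) > 2 and not g[2]:
                phased = False
        hap_rows.append(row)
        fdp = v.format("DP")
        dp_rows.append(np.full(n, -1, dtype=np.int32) if fdp is None
                       else fdp.reshape(-1).astype(np.int32))
        fgq = v.format("GQ")
        gq_rows.append(np.full(n, -1, dtype=np.int32) if fgq is None
                       else fgq.reshape(-1).astype(np.int32))
    vcf.close()

    for c in chroms:
        if c not in scaff_len:
            scaff_order.append(c)
            scaff_len[c] = 0
    scaffold_ids = scaff_order
    idx = {c: i for i, c in enumerate(scaffold_ids)}

    n_sites = len(positions)
    site_scaffold = np.array([idx[c] for c in chroms], dtype=np.int32)
    haps = (np.vstack(hap_rows) if n_sites
            else np.zeros((0, 2 * n), dtype=np.int8))
    dp = (np.vstack(dp_rows) if n_sites else np.zeros((0, n), dtype=np.int32))
    gq = (np.vstack(gq_rows) if n_sites else np.zeros((0, n), dtype=np.int32))

    ancestral = np.full(n_sites, -1, dtype=np.int8)
    truth_path = path + ".truth.tsv"
    if os.path.exists(truth_path) and n_sites:
        tr = pd.read_csv(truth_path, sep="\t")
        key = {(c, p): a for c, p, a in zip(tr["scaffold"], tr["pos"],
                                            tr["ancestral"])}
        for s in range(n_sites):
            a = key.get((chroms[s], positions[s]))
            if a == ref[s]:
                ancestral[s] = 0
            elif a == alt[s]:
                ancestral[s] = 1

    pops = ["" for _ in samples]
    samp_path = path + ".samples.tsv"
    if os.path.exists(samp_path):
        sm = pd.read_csv(samp_path, sep="\t")
        pop_of = dict(zip(sm["sample"].astype(str), sm["population"].astype(str)))
        pops = [pop_of.get(s, "") for s in samples]

    return GenotypeDataset(
        scaffold_ids=scaffold_ids,
        scaffold_lengths=np.array([scaff_len[c] for c in scaffold_ids],
                                  dtype=np.int64),
        site_scaffold=site_scaffold,
        positions=np.array(positions, dtype=np.int64),
        ref=np.array(ref, dtype="<U1"),
        alt=np.array(alt, dtype="<U1"),
        haplotypes=haps,
        dp=dp, gq=gq,
        mq=np.array(mq, dtype=float),
        ancestral=ancestral,
        sample_ids=samples,
        sample_population=pops,
        phased=phased,
    )
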