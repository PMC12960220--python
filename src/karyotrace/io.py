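"""Readers and writers for every external format the toolkit touches.

Formats: VCF (parents, via cyvcf2), TSV (BAF matrices, genotype tables,
ploidy calls, genetic maps, centromeres), BED (hotspots, crossovers),
bedGraph (replication timing), JSON (run metadata).

Coordinate conventions: SNP positions are 1-based; BED/bedGraph are
0-based half-open.  A crossover between flanking informative SNPs at
1-based positions L and R is written as BED interval [L-1, R).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
from cyvcf2 import VCF

from .datatypes import (CallSet, CrossoverEvent, EmbryoBAF, GeneticMap,
                        IntervalTrack, PloidyCall, SNPPanel)
from . import hmm

log = logging.getLogger("karyotrace")


# ---------------------------------------------------------------------------
# parent genotypes
# ---------------------------------------------------------------------------

def read_parent_genotypes(path, fmt: str | None = None,
                          mother: str | None = None,
                          father: str | None = None) -> SNPPanel:
    """Read the two parental genotypes from a VCF or a genotype TSV.

    The VCF must contain exactly two samples (mother first unless the
    sample names are given).  Multi-allelic sites and sites with a
    missing genotype in either parent are dropped (count logged).
    Phase flags are taken from the VCF phasing separators ('|' vs '/').
    """
    path = Path(path)
    if fmt is None:
        fmt = "vcf" if ".vcf" in path.suffixes or path.suffix == ".vcf" else "tsv"
    if fmt == "vcf":
        return _read_parent_vcf(path, mother, father)
    if fmt == "tsv":
        return _read_parent_tsv(path)
    raise ValueError(f"unknown parent genotype format {fmt!r}")


def _read_parent_vcf(path: Path, mother, father) -> SNPPanel:
    vcf = VCF(str(path))
    samples = list(vcf.samples)
    if len(samples) != 2:
        raise ValueError(f"two parent samples required, found {len(samples)}")
    if mother is None:
        mother, father = samples
    mi, fi = samples.index(mother), samples.index(father)

    chroms, poss, refs, alts = [], [], [], []
    mats, pats, mph, pph = [], [], [], []
    dropped = 0
    last = {}
    for v in vcf:
        if len(v.ALT) != 1:
            dropped += 1
            continue
        gm, gf = v.genotypes[mi], v.genotypes[fi]
        alleles = (gm[0], gm[1], gf[0], gf[1])
        if any(a < 0 or a > 1 for a in alleles):
            dropped += 1
            continue
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise ValueError(f"unsorted VCF: {v.CHROM}:{v.POS}")
        last[v.CHROM] = v.POS
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(v.ALT[0])
        mats.append((gm[0], gm[1]))
        pats.append((gf[0], gf[1]))
        mph.append(bool(gm[2]))
        pph.append(bool(gf[2]))
    if dropped:
        log.info("read_parent_genotypes: dropped %d missing/multi-allelic sites", dropped)
    if not poss:
        raise ValueError(f"no usable biallelic sites in {path}")
    return SNPPanel(
        chrom=np.array(chroms, dtype=object), pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype=object), alt=np.array(alts, dtype=object),
        mat_haps=np.array(mats, dtype=np.int8).T, pat_haps=np.array(pats, dtype=np.int8).T,
        mat_phased=all(mph), pat_phased=all(pph),
    )


def _read_parent_tsv(path: Path) -> SNPPanel:
    """Genotype table: columns chrom, pos, ref, alt, mother, father with
    GT strings such as '0|1' (phased) or '0/1' (unphased)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    need = {"chrom", "pos", "ref", "alt", "mother", "father"}
    if not need.issubset(df.columns):
        raise ValueError(f"genotype TSV must have columns {sorted(need)}")

    def parse(col):
        haps, phased = [], True
        keep = []
        for gt in df[col].astype(str):
            sep = "|" if "|" in gt else "/"
            if sep == "/":
                phased = False
            parts = gt.split(sep)
            ok = len(parts) == 2 and all(p in ("0", "1") for p in parts)
            keep.append(ok)
            haps.append((int(parts[0]), int(parts[1])) if ok else (0, 0))
        return np.array(haps, dtype=np.int8).T, phased, np.array(keep)

    mat, mat_ph, mkeep = parse("mother")
    pat, pat_ph, pkeep = parse("father")
    keep = mkeep & pkeep
    if (~keep).sum():
        log.info("read_parent_genotypes: dropped %d missing-genotype sites",
                 int((~keep).sum()))
    return SNPPanel(
        chrom=df["chrom"].to_numpy(dtype=object)[keep],
        pos=df["pos"].to_numpy(np.int64)[keep],
        ref=df["ref"].to_numpy(dtype=object)[keep],
        alt=df["alt"].to_numpy(dtype=object)[keep],
        mat_haps=mat[:, keep], pat_haps=pat[:, keep],
        mat_phased=mat_ph, pat_phased=pat_ph,
    )


def write_parent_vcf(panel: SNPPanel, path, mother: str = "MOTHER",
                     father: str = "FATHER") -> None:
    """Write the panel as a minimal two-sample VCF (text)."""
    sep_m = "|" if panel.mat_phased else "/"
    sep_p = "|" if panel.pat_phased else "/"
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in panel.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{mother}\t{father}\n")
        for i in range(panel.n_sites):
            gm = f"{panel.mat_haps[0, i]}{sep_m}{panel.mat_haps[1, i]}"
            gf = f"{panel.pat_haps[0, i]}{sep_p}{panel.pat_haps[1, i]}"
            fh.write(f"{panel.chrom[i]}\t{panel.pos[i]}\t.\t{panel.ref[i]}\t"
                     f"{panel.alt[i]}\t.\t.\t.\tGT\t{gm}\t{gf}\n")


# ---------------------------------------------------------------------------
# embryo BAF tables
# ---------------------------------------------------------------------------

def read_embryo_baf(path, panel: SNPPanel | None = None,
                    family_id: str = "f0") -> list[EmbryoBAF]:
    """Read per-embryo BAF vectors from a long or wide TSV.

    Long format: columns embryo_id, family_id, chrom, pos, baf
    (optionally maternal_age, paternal_age).  Wide format: chrom, pos,
    then one column per embryo.  Values outside [0, 1] are an error
    naming the site; "NA"/empty entries are masked as missing.  When a
    panel is given, rows are aligned to panel site order and unknown
    site keys are an error.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    long_format = "embryo_id" in df.columns
    if long_format:
        vals = df["baf"].astype(float)
        bad = df[(vals < 0) | (vals > 1)]
    else:
        embryo_cols = [c for c in df.columns if c not in ("chrom", "pos")]
        melted = df.melt(id_vars=["chrom", "pos"], value_vars=embryo_cols,
                         value_name="baf")
        v = melted["baf"].astype(float)
        bad = melted[(v < 0) | (v > 1)]
    if bad is not None and len(bad):
        row = bad.iloc[0]
        raise ValueError(f"BAF outside [0, 1] at {row['chrom']}:{int(row['pos'])}")

    def align(sub: pd.DataFrame) -> np.ndarray:
        if panel is None:
            return sub["baf"].to_numpy(dtype=np.float64)
        key = pd.MultiIndex.from_arrays([panel.chrom, panel.pos])
        sub = sub.set_index(["chrom", "pos"])
        unknown = sub.index.difference(key)
        if len(unknown):
            c, p = unknown[0]
            raise ValueError(f"BAF site {c}:{p} not present in the panel")
        return sub.reindex(key)["baf"].to_numpy(dtype=np.float64)

    out = []
    if long_format:
        for (eid, fid), sub in df.groupby(["embryo_id", "family_id"], sort=False):
            out.append(EmbryoBAF(
                embryo_id=str(eid), family_id=str(fid), baf=align(sub),
                maternal_age=float(sub["maternal_age"].iloc[0]) if "maternal_age" in sub else float("nan"),
                paternal_age=float(sub["paternal_age"].iloc[0]) if "paternal_age" in sub else float("nan"),
            ))
    else:
        for col in [c for c in df.columns if c not in ("chrom", "pos")]:
            sub = df[["chrom", "pos", col]].rename(columns={col: "baf"})
            out.append(EmbryoBAF(embryo_id=str(col), family_id=family_id,
                                 baf=align(sub)))
    return out


def write_embryo_baf(embryos: list[EmbryoBAF], panel: SNPPanel, path) -> None:
    """Write a wide BAF TSV aligned to panel site order."""
    df = pd.DataFrame({"chrom": panel.chrom, "pos": panel.pos})
    for e in embryos:
        df[e.embryo_id] = e.baf
    df.to_csv(path, sep="\t", index=False, na_rep="NA", float_format="%.6g")


# ---------------------------------------------------------------------------
# genetic map, centromeres
# ---------------------------------------------------------------------------

def read_genetic_map(path) -> GeneticMap:
    """3-column TSV: chrom, pos_bp, pos_cM (header optional)."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={0: str})
    if not {"chrom", "pos_bp", "pos_cm"}.issubset(c.lower() for c in df.columns):
        df = pd.read_csv(path, sep="\t", comment="#", header=None,
                         names=["chrom", "pos_bp", "pos_cM"], dtype={0: str})
    df.columns = [c if c.lower() != "pos_cm" else "pos_cM" for c in df.columns]
    anchors = {str(c): (g["pos_bp"].to_numpy(float), g["pos_cM"].to_numpy(float))
               for c, g in df.groupby("chrom", sort=False)}
    return GeneticMap(anchors)


def write_genetic_map(gmap: GeneticMap, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos_bp\tpos_cM\n")
        for c in gmap.chromosomes():
            bp, cm = gmap.anchors(c)
            for b, m in zip(bp, cm):
                fh.write(f"{c}\t{int(b)}\t{m:.17g}\n")


def read_centromeres(path) -> dict[str, int]:
    """3-column TSV chrom, start, end (0-based); midpoint is used."""
    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end"], dtype={0: str})
    return {r.chrom: int((r.start + r.end) // 2) for r in df.itertuples()}


# ---------------------------------------------------------------------------
# interval tracks (BED / bedGraph)
# ---------------------------------------------------------------------------

def read_interval_track(path, kind: str = "bed") -> IntervalTrack:
    """Read hotspot BED (merged) or a valued bedGraph track.

    0-based half-open intervals are preserved; hotspot intervals are
    merged after load.  Malformed lines raise with their line number.
    """
    rows: dict[str, list] = {}
    want_value = kind == "bedgraph"
    with open(path) as fh:
        for ln, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < (4 if want_value else 3):
                raise ValueError(f"{path}:{ln}: expected at least "
                                 f"{4 if want_value else 3} columns")
            try:
                chrom, start, end = parts[0], int(parts[1]), int(parts[2])
                value = float(parts[3]) if want_value else None
            except ValueError as err:
                raise ValueError(f"{path}:{ln}: malformed line ({err})") from None
            if end <= start:
                raise ValueError(f"{path}:{ln}: interval end <= start")
            rows.setdefault(chrom, []).append((start, end, value))
    iv = {}
    for chrom, triples in rows.items():
        s = np.array([t[0] for t in triples], np.int64)
        e = np.array([t[1] for t in triples], np.int64)
        v = None if not want_value else np.array([t[2] for t in triples])
        iv[chrom] = (s, e, v)
    track = IntervalTrack(iv)
    return track.merged() if kind == "bed" else track


# ---------------------------------------------------------------------------
# call sets
# ---------------------------------------------------------------------------

_PLOIDY_COLS = ["embryo_id", "chrom", "call", "copy_number", "origin", "meiotic_class"]


def write_callset(calls: CallSet, out_dir) -> dict[str, Path]:
    """Write ploidy TSV + crossover BED + metadata JSON.

    Crossover BED: start = 0-based position of the left flanking
    informative SNP, end = 0-based position of the right flanking SNP
    + 1, name = embryo_id|parent, score = min flank posterior × 1000;
    the exact flank posteriors ride along as extra columns so that the
    reader round-trips losslessly.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {"ploidy": out / "ploidy_calls.tsv",
             "crossovers": out / "crossovers.bed",
             "metadata": out / "metadata.json"}

    rows = []
    for c in calls.ploidy_calls:
        row = {"embryo_id": c.embryo_id, "chrom": c.chrom, "call": c.call,
               "copy_number": "" if c.copy_number is None else c.copy_number,
               "origin": c.origin or "", "meiotic_class": c.meiotic_class}
        for h in hmm.HYPOTHESES:
            row[f"post_{h}"] = f"{c.posteriors.get(h, float('nan')):.17g}"
        rows.append(row)
    cols = _PLOIDY_COLS + [f"post_{h}" for h in hmm.HYPOTHESES]
    pd.DataFrame(rows, columns=cols).to_csv(paths["ploidy"], sep="\t", index=False)

    with open(paths["crossovers"], "w") as fh:
        fh.write("#chrom\tstart\tend\tname\tscore\tstrand\tgamma_left\tgamma_right\n")
        for ev in calls.crossovers:
            score = int(round(min(ev.gamma_left, ev.gamma_right) * 1000))
            fh.write(f"{ev.chrom}\t{ev.left - 1}\t{ev.right}\t"
                     f"{ev.embryo_id}|{ev.parent}\t{score}\t.\t"
                     f"{ev.gamma_left:.17g}\t{ev.gamma_right:.17g}\n")

    with open(paths["metadata"], "w") as fh:
        json.dump(calls.metadata, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths


def read_callset(out_dir) -> CallSet:
    """Inverse of :func:`write_callset` (lossless round trip)."""
    out = Path(out_dir)
    df = pd.read_csv(out / "ploidy_calls.tsv", sep="\t",
                     dtype={"chrom": str, "embryo_id": str},
                     keep_default_na=False, float_precision="round_trip")
    ploidy = []
    for r in df.itertuples():
        posteriors = {h: float(getattr(r, f"post_{h}")) for h in hmm.HYPOTHESES}
        cn = getattr(r, "copy_number")
        ploidy.append(PloidyCall(
            embryo_id=r.embryo_id, chrom=r.chrom, posteriors=posteriors,
            call=r.call, copy_number=None if cn == "" else int(cn),
            origin=r.origin or None, meiotic_class=r.meiotic_class))

    events = []
    with open(out / "crossovers.bed") as fh:
        for line in fh:
            if line.startswith("#"):
                continue
            chrom, start, end, name, _score, _strand, gl, gr = line.rstrip("\n").split("\t")
            embryo_id, parent = name.rsplit("|", 1)
            events.append(CrossoverEvent(
                embryo_id=embryo_id, parent=parent, chrom=chrom,
                left=int(start) + 1, right=int(end),
                gamma_left=float(gl), gamma_right=float(gr)))

    with open(out / "metadata.json") as fh:
        metadata = json.load(fh)
    return CallSet(ploidy_calls=ploidy, crossovers=events, metadata=metadata)


def write_truth_table(truths, path) -> None:
    """Simulator ground truth as TSV (embryo, mode, per-chromosome k)."""
    rows = []
    for t in truths:
        for chrom, ct in t.chroms.items():
            rows.append({
                "embryo_id": t.embryo_id, "family_id": t.family_id,
                "embryo_mode": t.mode, "chrom": chrom, "chrom_mode": ct.mode,
                "k": ct.k,
                "maternal_crossovers": ",".join(f"{x:.0f}" for x in ct.maternal_crossovers),
                "paternal_crossovers": ",".join(f"{x:.0f}" for x in ct.paternal_crossovers),
            })
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
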