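"""Plain-text readers/writers for every pipeline artifact.

Schemas:

* CpG map: ``sites.bed`` (BED3, width-2 site intervals) + ``sites.tsv``
  (region class per site) + ``windows.tsv`` (per-window GC, CpG density,
  class, island flag) + ``chroms.tsv`` (name, length, window_bp).
* tissue methylomes: ``<values>.tsv`` (site index + one column per sample)
  and ``<samples>.tsv`` (sample_id, group).
* fragments: TSV with sample_id, chrom, start, end, cpg_positions,
  cpg_states (comma-joined; empty for CpG-free fragments).
* cohort table: CSV, one row per plasma sample.
* DMRs: BED6+ — chrom, start, end, name, score = -log10(q), strand ".",
  then n_cpgs, delta, direction, p, q, mean_beta_mal, mean_beta_ben.
* marker profiles: CSV, rows = samples, columns = DMR ids (+ counts CSV).
* model result: JSON.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .dmr import DMR
from .fragments import FragmentSet
from .genome import REGION_CLASSES, CpGMap
from .models import ModelResult
from .origin import MarkerProfileSet
from .simulate import CohortRecord, PlasmaSample, TissueMethylome


# ----------------------------------------------------------------- CpG map

def write_cpg_map(cpg_map: CpGMap, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chrom = cpg_map.site_chrom
    sites = pd.DataFrame(
        {
            "chrom": [cpg_map.chrom_names[c] for c in chrom],
            "start": cpg_map.site_pos,
            "end": cpg_map.site_pos + 2,
        }
    )
    sites.to_csv(outdir / "sites.bed", sep="\t", header=False, index=False)
    pd.DataFrame(
        {"region_class": [REGION_CLASSES[r] for r in cpg_map.site_region]}
    ).to_csv(outdir / "sites.tsv", sep="\t", index=False)
    wchrom = cpg_map.window_chrom
    windows = pd.DataFrame(
        {
            "chrom": [cpg_map.chrom_names[c] for c in wchrom],
            "start": cpg_map.window_start,
            "end": cpg_map.window_start + cpg_map.window_bp,
            "gc": cpg_map.window_gc,
            "cpg_density": cpg_map.window_cpg_density,
            "region_class": [REGION_CLASSES[r] for r in cpg_map.window_region],
            "is_island": cpg_map.window_is_island.astype(int)
            if cpg_map.window_is_island is not None
            else 0,
        }
    )
    windows.to_csv(outdir / "windows.tsv", sep="\t", index=False)
    pd.DataFrame(
        {
            "chrom": cpg_map.chrom_names,
            "length": cpg_map.chrom_lengths,
            "window_bp": cpg_map.window_bp,
        }
    ).to_csv(outdir / "chroms.tsv", sep="\t", index=False)


def read_cpg_map(indir) -> CpGMap:
    indir = Path(indir)
    chroms = pd.read_csv(indir / "chroms.tsv", sep="\t")
    names = tuple(chroms["chrom"].astype(str))
    lookup = {n: i for i, n in enumerate(names)}
    window_bp = int(chroms["window_bp"].iloc[0])
    sites = pd.read_csv(indir / "sites.bed", sep="\t",
                        names=["chrom", "start", "end"])
    site_region_names = pd.read_csv(indir / "sites.tsv", sep="\t")["region_class"]
    windows = pd.read_csv(indir / "windows.tsv", sep="\t")

    site_chrom = sites["chrom"].map(lookup).to_numpy()
    order = np.lexsort((sites["start"].to_numpy(), site_chrom))
    site_pos = sites["start"].to_numpy(np.int64)[order]
    region = np.array(
        [REGION_CLASSES.index(r) for r in site_region_names], dtype=np.uint8
    )[order]
    site_offsets = np.concatenate(
        [[0], np.cumsum(np.bincount(site_chrom, minlength=len(names)))]
    ).astype(np.int64)
    wchrom = windows["chrom"].map(lookup).to_numpy()
    window_offsets = np.concatenate(
        [[0], np.cumsum(np.bincount(wchrom, minlength=len(names)))]
    ).astype(np.int64)
    return CpGMap(
        chrom_names=names,
        chrom_lengths=chroms["length"].to_numpy(np.int64),
        site_pos=site_pos,
        site_offsets=site_offsets,
        site_region=region,
        window_bp=window_bp,
        window_offsets=window_offsets,
        window_gc=windows["gc"].to_numpy(float),
        window_cpg_density=windows["cpg_density"].to_numpy(float),
        window_region=np.array(
            [REGION_CLASSES.index(r) for r in windows["region_class"]], dtype=np.uint8
        ),
        window_is_island=windows["is_island"].to_numpy(bool),
    )


# ------------------------------------------------------------- methylomes

def write_methylomes(tissues: list[TissueMethylome], values_path, samples_path) -> None:
    df = pd.DataFrame({t.sample_id: t.beta for t in tissues})
    df.insert(0, "site", np.arange(df.shape[0]))
    df.to_csv(values_path, sep="\t", index=False, float_format="%.5f")
    pd.DataFrame(
        {"sample_id": [t.sample_id for t in tissues], "group": [t.group for t in tissues]}
    ).to_csv(samples_path, sep="\t", index=False)


def read_methylomes(values_path, samples_path) -> list[TissueMethylome]:
    values = pd.read_csv(values_path, sep="\t").drop(columns=["site"])
    sheet = pd.read_csv(samples_path, sep="\t")
    groups = dict(zip(sheet["sample_id"], sheet["group"]))
    return [
        TissueMethylome(sample_id=c, group=groups[c], beta=values[c].to_numpy(float))
        for c in values.columns
    ]


# -------------------------------------------------------------- fragments

def write_fragments(samples: list[PlasmaSample], path) -> None:
    rows = []
    for s in samples:
        f = s.fragments
        off = f.cpg_offsets
        for i in range(len(f)):
            lo, hi = off[i], off[i + 1]
            rows.append(
                (
                    s.sample_id,
                    f.chrom_names[f.chrom[i]],
                    int(f.start[i]),
                    int(f.end[i]),
                    ",".join(map(str, f.cpg_pos[lo:hi])),
                    ",".join(map(str, f.cpg_state[lo:hi])),
                )
            )
    pd.DataFrame(
        rows, columns=["sample_id", "chrom", "start", "end", "cpg_positions", "cpg_states"]
    ).to_csv(path, sep="\t", index=False)


def read_fragments(path, chrom_names: tuple[str, ...] | None = None) -> list[PlasmaSample]:
    df = pd.read_csv(path, sep="\t", dtype={"cpg_positions": str, "cpg_states": str})
    df["cpg_positions"] = df["cpg_positions"].fillna("")
    df["cpg_states"] = df["cpg_states"].fillna("")
    if chrom_names is None:
        chrom_names = tuple(dict.fromkeys(df["chrom"].astype(str)))
    lookup = {c: i for i, c in enumerate(chrom_names)}
    samples = []
    for sid, sub in df.groupby("sample_id", sort=False):
        pos_lists = [
            np.fromstring(p, dtype=np.int64, sep=",") if p else np.array([], np.int64)
            for p in sub["cpg_positions"]
        ]
        counts = np.array([p.size for p in pos_lists])
        state_lists = [
            np.fromstring(s, dtype=np.int64, sep=",") if s else np.array([], np.int64)
            for s in sub["cpg_states"]
        ]
        fragset = FragmentSet(
            chrom=sub["chrom"].map(lookup).to_numpy(),
            start=sub["start"].to_numpy(np.int64),
            end=sub["end"].to_numpy(np.int64),
            cpg_offsets=np.concatenate([[0], np.cumsum(counts)]),
            cpg_pos=np.concatenate(pos_lists) if pos_lists else np.array([], np.int64),
            cpg_state=np.concatenate(state_lists) if state_lists else np.array([], np.int64),
            chrom_names=chrom_names,
        )
        samples.append(PlasmaSample(sample_id=str(sid), label=None, fragments=fragset))
    return samples


# ------------------------------------------------------------ cohort table

def write_cohort(records: list[CohortRecord], path) -> None:
    pd.DataFrame([vars(r) for r in records]).to_csv(path, index=False)


def read_cohort(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"stage": str, "birads_sub": str})
    return df.set_index("sample_id")


# ------------------------------------------------------------------- DMRs

def write_dmrs(dmrs: list[DMR], path) -> None:
    rows = [
        (
            d.chrom, d.start, d.end, d.name,
            round(-np.log10(max(d.q_value, 1e-300)), 4), ".",
            d.n_cpgs, f"{d.delta:.5f}", d.direction,
            f"{d.p_value:.4g}", f"{d.q_value:.4g}",
            f"{d.mean_beta_mal:.5f}", f"{d.mean_beta_ben:.5f}",
        )
        for d in dmrs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)


def read_dmrs(path) -> list[DMR]:
    cols = [
        "chrom", "start", "end", "name", "score", "strand",
        "n_cpgs", "delta", "direction", "p", "q", "mean_mal", "mean_ben",
    ]
    df = pd.read_csv(path, sep="\t", names=cols)
    return [
        DMR(
            chrom=str(r.chrom), start=int(r.start), end=int(r.end),
            n_cpgs=int(r.n_cpgs),
            mean_beta_mal=float(r.mean_mal), mean_beta_ben=float(r.mean_ben),
            delta=float(r.delta), direction=str(r.direction),
            p_value=float(r.p), q_value=float(r.q),
        )
        for r in df.itertuples()
    ]


# --------------------------------------------------------------- profiles

def write_profiles(profiles: MarkerProfileSet, ratios_path, counts_path=None) -> None:
    profiles.ratios.to_csv(ratios_path, index_label="sample_id", float_format="%.5f")
    if counts_path is not None:
        profiles.counts.to_csv(counts_path, index_label="sample_id")


def read_profiles(ratios_path) -> pd.DataFrame:
    return pd.read_csv(ratios_path).set_index("sample_id")


# ------------------------------------------------------------ model result

def write_model_result(result: ModelResult, path) -> None:
    payload = {
        "auc": result.auc,
        "auc_ci": list(result.auc_ci),
        "threshold": result.threshold,
        "confusion": {"tp": result.tp, "fp": result.fp, "tn": result.tn, "fn": result.fn},
        "sensitivity": result.sensitivity,
        "specificity": result.specificity,
        "accuracy": result.accuracy,
        "stage_detection": result.stage_detection,
        "roc": result.roc,
    }
    if result.scores is not None and isinstance(result.scores, pd.Series):
        payload["scores"] = {str(k): float(v) for k, v in result.scores.items()}
    Path(path).write_text(json.dumps(payload, indent=2))
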