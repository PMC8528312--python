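"""Batch screening of many CDSs for creatable overlapping reading frames.

For each gene and each stringency level the screen records the earliest
position at which a new reading frame can be opened — earlier positions
mean larger overlaps and better protection — and summarises the results as
cumulative position distributions and per-group means with 95% CIs.
"""

from __future__ import annotations

import warnings
from concurrent.futures import ProcessPoolExecutor
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy import stats as sstats

from riboverlap.design import RibosorConfig, Stringency, design
from riboverlap.seqcore import CDSRecord, SequenceError

STRINGENCIES = (Stringency.S0, Stringency.S1, Stringency.S2plus)


def _screen_one(args):
    cds, configs = args
    row = {"cds_id": cds.id, "length_nt": len(cds)}
    for stringency, config in configs.items():
        cands = design(cds, config)
        key = stringency.value
        if cands:
            best = cands[0]
            row[f"earliest_start_nt_{key}"] = best.start_nt
            row[f"best_overlap_fraction_{key}"] = best.overlap_fraction
        else:
            row[f"earliest_start_nt_{key}"] = None
            row[f"best_overlap_fraction_{key}"] = 0.0
    return row


def screen_genes(
    records,
    config: RibosorConfig = RibosorConfig(),
    stringencies=STRINGENCIES,
    mapping: dict[str, str] | None = None,
    workers: int = 1,
) -> pd.DataFrame:
    """One row per valid CDS with earliest creatable overlap per stringency.

    Invalid CDSs are skipped with a warning and counted in the frame's
    ``attrs['n_skipped']``. ``mapping`` attaches an optional category label
    per gene id (e.g. COG category or species; computing such mappings is
    external). Output order follows input order regardless of worker count.
    """
    configs = {s: replace(config, stringency=s) for s in stringencies}
    valid: list[CDSRecord] = []
    n_skipped = 0
    for rec in records:
        if isinstance(rec, CDSRecord):
            valid.append(rec)
            continue
        try:
            valid.append(CDSRecord(*rec) if isinstance(rec, tuple) else rec)
        except SequenceError as exc:
            warnings.warn(f"skipping invalid CDS: {exc}")
            n_skipped += 1
    jobs = [(cds, configs) for cds in valid]
    if workers > 1:
        with ProcessPoolExecutor(max_workers=workers) as pool:
            rows = list(pool.map(_screen_one, jobs))
    else:
        rows = [_screen_one(j) for j in jobs]
    columns = ["cds_id", "length_nt"]
    for s in stringencies:
        columns += [f"earliest_start_nt_{s.value}", f"best_overlap_fraction_{s.value}"]
    df = pd.DataFrame(rows, columns=columns)
    if mapping:
        df["category"] = df["cds_id"].map(mapping)
    df.attrs["n_skipped"] = n_skipped
    return df


def cumulative_position_distribution(
    rows: pd.DataFrame, stringency: Stringency
) -> pd.DataFrame:
    """Fraction of genes whose earliest candidate lies at or before a
    relative position, as a nondecreasing step function on [0, 1].

    Genes with no candidate contribute to no step; their fraction is in
    ``attrs['no_candidate_fraction']``. Absolute positions are included for
    reference.
    """
    if rows.empty:
        raise ValueError("no screen rows")
    key = f"earliest_start_nt_{stringency.value}"
    pos = rows[key]
    have = rows[pos.notna()]
    n = len(rows)
    rel = (have[key].astype(float) / have["length_nt"]).sort_values()
    steps = []
    for i, (idx, r) in enumerate(rel.items(), start=1):
        steps.append(
            {
                "relative_position": r,
                "absolute_position_nt": int(rows.loc[idx, key]),
                "cumulative_fraction": i / n,
            }
        )
    out = pd.DataFrame(
        steps, columns=["relative_position", "absolute_position_nt", "cumulative_fraction"]
    )
    out.attrs["no_candidate_fraction"] = 1.0 - len(have) / n
    return out


def group_summary(
    rows: pd.DataFrame, group_key: str, stringency: Stringency = Stringency.S1
) -> pd.DataFrame:
    """Per-group mean best overlap fraction with a 95% confidence interval.

    t-interval for n < 30, normal approximation otherwise. Single-member
    groups get a degenerate CI and a flag.
    """
    key = f"best_overlap_fraction_{stringency.value}"
    out = []
    for group, sub in rows.groupby(group_key):
        vals = sub[key].astype(float).to_numpy()
        n = len(vals)
        mean = float(np.mean(vals))
        if n == 1:
            out.append(
                {
                    "group": group,
                    "n": 1,
                    "mean": mean,
                    "ci_lo": mean,
                    "ci_hi": mean,
                    "degenerate": True,
                }
            )
            continue
        se = float(np.std(vals, ddof=1)) / np.sqrt(n)
        crit = sstats.t.ppf(0.975, n - 1) if n < 30 else sstats.norm.ppf(0.975)
        out.append(
            {
                "group": group,
                "n": n,
                "mean": mean,
                "ci_lo": mean - crit * se,
                "ci_hi": mean + crit * se,
                "degenerate": False,
            }
        )
    return pd.DataFrame(out, columns=["group", "n", "mean", "ci_lo", "ci_hi", "degenerate"])
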