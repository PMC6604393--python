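"""Conjugation-efficiency normalisation and CRISPR interference verdicts.

Transconjugant colony counts from a plate assay are normalised to a
reference cell — by convention the wild type receiving the non-target
control plasmid (pNT) — so the reference mean is 1 by construction.  The
summary reports mean +/- SE over biological replicates with plug-in
normalisation (reference-mean uncertainty is not propagated).  Interference
is called per strain and PAM by comparing the target-plasmid (pT) mean to
the matched pNT mean: a near-empty plate (ratio below threshold) means the
CRISPR system destroyed the incoming plasmid.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

COUNT_COLUMNS = ["strain", "plasmid", "pam", "replicate", "colonies"]


def read_counts_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in COUNT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"counts table missing columns: {missing}")
    if (df["colonies"] < 0).any():
        raise ValueError("negative colony counts")
    return df


def normalize(records: pd.DataFrame,
              reference: tuple[str, str] = ("WT", "pNT")) -> pd.DataFrame:
    """Per-(strain, plasmid, pam) normalised efficiency summary.

    Each replicate count is divided by the mean count of the reference
    (strain, plasmid) cell; SE = sd/sqrt(n), reported as NaN for a single
    replicate.
    """
    ref_strain, ref_plasmid = reference
    ref = records[(records["strain"] == ref_strain)
                  & (records["plasmid"] == ref_plasmid)]
    if len(ref) == 0:
        raise ValueError(f"no replicates for reference cell {reference}")
    ref_mean = ref["colonies"].mean()
    if ref_mean <= 0:
        raise ValueError("reference cell mean is zero")

    rows = []
    for (strain, plasmid, pam), grp in records.groupby(
            ["strain", "plasmid", "pam"], dropna=False, sort=True):
        norm = grp["colonies"] / ref_mean
        n = len(norm)
        rows.append({
            "strain": strain, "plasmid": plasmid, "pam": pam, "n": n,
            "mean_efficiency": float(norm.mean()),
            "se": float(norm.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan"),
        })
    out = pd.DataFrame(rows)
    out.attrs["reference"] = reference
    return out


def interference_call(summary: pd.DataFrame, threshold: float = 0.1) -> pd.DataFrame:
    """Per-(strain, pam) interference verdict from the pT/pNT efficiency ratio.

    ``interference`` when ratio < threshold, else ``no interference``.  Cells
    lacking a matched pT or pNT summary are reported with a warning flag.
    """
    if not 0 < threshold:
        raise ValueError("threshold must be positive")
    rows = []
    for strain, grp in summary.groupby("strain", sort=True):
        nt = grp[grp["plasmid"] == "pNT"]
        if len(nt) == 0:
            rows.append({"strain": strain, "pam": None, "ratio": float("nan"),
                         "verdict": "missing pNT", "warning": True})
            continue
        nt_mean = nt["mean_efficiency"].mean()
        t = grp[grp["plasmid"] == "pT"]
        if len(t) == 0:
            rows.append({"strain": strain, "pam": None, "ratio": float("nan"),
                         "verdict": "missing pT", "warning": True})
            continue
        for row in t.itertuples(index=False):
            if nt_mean == 0:
                ratio = float("nan")
            else:
                ratio = row.mean_efficiency / nt_mean
            verdict = "interference" if ratio < threshold else "no interference"
            rows.append({"strain": strain, "pam": row.pam, "ratio": float(ratio),
                         "verdict": verdict, "warning": False})
    out = pd.DataFrame(rows)
    out.attrs["threshold"] = threshold
    return out


def simulate_counts(rng, strains=("WT", "mutant"), pams=("GTC", "GTA", "AGC"),
                    n_replicates: int = 3, lam_pt: float = 1.0,
                    lam_pnt: float = 60.0, mutant_factor: float = 0.5) -> pd.DataFrame:
    """Poisson colony counts for a plate assay with known ground truth.

    Functional PAMs (GTC/GTA) draw pT counts at ``lam_pt`` (interference);
    the AGC non-PAM behaves like the control at ``lam_pnt``.  Mutant strains
    conjugate at ``mutant_factor`` of the wild-type rate.
    """
    rows = []
    for strain in strains:
        scale = 1.0 if strain == "WT" else mutant_factor
        for rep in range(1, n_replicates + 1):
            rows.append({"strain": strain, "plasmid": "pNT", "pam": "none",
                         "replicate": rep,
                         "colonies": int(rng.poisson(lam_pnt * scale))})
        for pam in pams:
            lam = lam_pnt if pam == "AGC" else lam_pt
            for rep in range(1, n_replicates + 1):
                rows.append({"strain": strain, "plasmid": "pT", "pam": pam,
                             "replicate": rep,
                             "colonies": int(rng.poisson(lam * scale))})
    return pd.DataFrame(rows)
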