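"""Sex-chromosome detection from sexed read-depth tracks.

The statistic is the classic one for ZW (and XY) systems: per chromosome,
take the per-base median depth of each sample, normalize by the mean of
that sample's chromosome medians (removing library size), average the
normalized depths by sex, and compare sexes as log2(male:female).
Autosomes sit at log2 = 0, the Z at log2 = 1 (two male copies vs one
female copy), and the female-limited W collapses to ~0 male depth.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import CoverageTrack

DEFAULT_PSEUDOCOUNT = 0.01


def log2_mf(male_mean: float, female_mean: float, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> float:
    """log2((M + eps) / (F + eps)); the pseudocount keeps the W finite."""
    if male_mean < 0 or female_mean < 0:
        raise ValueError("normalized depths must be non-negative")
    return float(np.log2((male_mean + pseudocount) / (female_mean + pseudocount)))


def _group_tracks(
    tracks: list[CoverageTrack], manifest: dict[str, str]
) -> tuple[list[str], list[str], dict[tuple[str, str], CoverageTrack]]:
    samples = list(dict.fromkeys(t.sample_id for t in tracks))
    chroms = list(dict.fromkeys(t.chrom for t in tracks))
    for s in samples:
        if s not in manifest:
            raise ValueError(f"sample {s!r} missing from the manifest")
        if manifest[s] not in ("male", "female"):
            raise ValueError(f"sample {s!r} has unknown sex {manifest[s]!r}")
    for sex in ("male", "female"):
        if not any(manifest[s] == sex for s in samples):
            raise ValueError(f"no {sex} sample present; need >= 1 per sex")
    by_key = {(t.sample_id, t.chrom): t for t in tracks}
    for s in samples:
        for c in chroms:
            if (s, c) not in by_key:
                raise ValueError(f"sample {s!r} has no coverage track for chromosome {c!r}")
    return samples, chroms, by_key


def _sample_normalizers(
    samples: list[str], chroms: list[str], by_key: dict
) -> tuple[pd.DataFrame, pd.Series]:
    """Chromosome-median matrix (chrom x sample) and per-sample mean of medians."""
    med = pd.DataFrame(
        {s: [float(np.median(by_key[(s, c)].depths)) for c in chroms] for s in samples},
        index=pd.Index(chroms, name="chrom"),
    )
    return med, med.mean(axis=0)


def summarize_coverage(
    tracks: list[CoverageTrack],
    manifest: dict[str, str],
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """Per-chromosome coverage summary.

    Returns a DataFrame indexed by chromosome with per-sample median and
    normalized depths, sex means of normalized depth, and the log2 M:F
    ratio.  Medians include zero-depth bases.
    """
    samples, chroms, by_key = _group_tracks(tracks, manifest)
    med, normalizer = _sample_normalizers(samples, chroms, by_key)
    norm = med / normalizer
    males = [s for s in samples if manifest[s] == "male"]
    females = [s for s in samples if manifest[s] == "female"]
    out = pd.DataFrame(index=pd.Index(chroms, name="chrom"))
    for s in samples:
        out[f"median:{s}"] = med[s]
        out[f"norm:{s}"] = norm[s]
    out["male_mean"] = norm[males].mean(axis=1)
    out["female_mean"] = norm[females].mean(axis=1)
    out["log2_mf"] = [
        log2_mf(m, f, pseudocount) for m, f in zip(out["male_mean"], out["female_mean"])
    ]
    return out


def classify_chromosomes(
    summary: pd.DataFrame,
    *,
    autosome_band: float = 0.25,
    z_log2_min: float = 0.75,
    z_male_min: float = 0.5,
    w_log2_max: float = -0.75,
    w_male_max: float = 0.25,
    w_female_min: float = 0.5,
) -> pd.Series:
    """Label chromosomes autosome / Z / W / ambiguous from a coverage summary.

    Bands around the idealized expectations (0 for autosomes, 1 for Z,
    strongly negative for the W) are configurable; ambiguous is a valid
    outcome for anything between the bands.
    """
    labels = []
    for _, row in summary.iterrows():
        lg, m, f = row["log2_mf"], row["male_mean"], row["female_mean"]
        if lg <= w_log2_max or (m < w_male_max and f >= w_female_min):
            labels.append("W")
        elif lg >= z_log2_min and m >= z_male_min:
            labels.append("Z")
        elif abs(lg) < autosome_band:
            labels.append("autosome")
        else:
            labels.append("ambiguous")
    return pd.Series(labels, index=summary.index, name="inferred_class")


def windowed_ratio(
    tracks: list[CoverageTrack],
    manifest: dict[str, str],
    window_bp: int = 1000,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> pd.DataFrame:
    """log2 M:F of windowed median coverages in non-overlapping windows.

    Windows tile each chromosome; a final short window is retained and
    flagged partial.  Per-sample window medians are normalized by the same
    per-sample chromosome-median mean used chromosome-wide.
    """
    if window_bp < 1:
        raise ValueError("window_bp must be >= 1")
    samples, chroms, by_key = _group_tracks(tracks, manifest)
    _, normalizer = _sample_normalizers(samples, chroms, by_key)
    males = [s for s in samples if manifest[s] == "male"]
    females = [s for s in samples if manifest[s] == "female"]
    rows = []
    for c in chroms:
        length = len(by_key[(samples[0], c)].depths)
        n_full, rem = divmod(length, window_bp)
        starts = [i * window_bp for i in range(n_full)] + ([n_full * window_bp] if rem else [])
        # per-sample windowed medians, vectorized over full windows
        win_norm = {}
        for s in samples:
            d = by_key[(s, c)].depths
            meds = (
                np.median(d[: n_full * window_bp].reshape(n_full, window_bp), axis=1)
                if n_full
                else np.empty(0)
            )
            if rem:
                meds = np.append(meds, np.median(d[n_full * window_bp :]))
            win_norm[s] = meds / normalizer[s]
        m_mean = np.mean([win_norm[s] for s in males], axis=0)
        f_mean = np.mean([win_norm[s] for s in females], axis=0)
        for i, start in enumerate(starts):
            end = min(start + window_bp, length)
            rows.append(
                {
                    "chrom": c,
                    "start": start,
                    "end": end,
                    "log2_mf": log2_mf(float(m_mean[i]), float(f_mean[i]), pseudocount),
                    "partial": end - start < window_bp,
                }
            )
    return pd.DataFrame(rows)
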