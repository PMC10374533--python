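"""Archive-scale detection: thresholding, rain filter, active-learning loop.

A trained model is run over every 5-s segment of a recording archive.  Each
segment's Q75 score per class is compared with the per-site decision
threshold (score >= threshold counts as positive — the closed-bound
convention used package-wide).  Because low-SNR clicks in the flooded forest
are confused with rain, a posterior rain filter re-attributes any segment
that exceeds both the click threshold and the site's rain-filter threshold:
its click flag is cleared and the segment marked as rain-attributed.  Boat
flags are never touched by the filter.

The active-learning loop samples positively classified segments above a
threshold for manual review, exports audio snippets and spectrogram images,
and merges the verdicts (confirmations and corrections) back into the
training manifest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from botopam.annotations import TARGET_CLASSES
from botopam.evaluation import q75_scores

DETECTIONS_COLUMNS = [
    "segment_id",
    "site",
    "start_time_iso",
    "q75_click",
    "q75_boat",
    "q75_rain",
    "flag_click",
    "flag_boat",
    "flag_rain",
    "rain_attributed",
]


@dataclass
class ThresholdTable:
    """Per-site, per-class decision thresholds plus optional rain filter.

    ``thresholds[site][class]`` is the decision threshold; ``rain_filter``
    maps a site to the rain-filter threshold or is absent when the filter is
    not applied there.  Every monitored site must at least carry click and
    boat thresholds.
    """

    thresholds: dict
    rain_filter: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for site, table in self.thresholds.items():
            for cls in ("click", "boat"):
                if cls not in table:
                    raise ValueError(f"site {site!r} is missing a {cls} threshold")
            for cls, value in table.items():
                if not 0.0 <= value <= 1.0:
                    raise ValueError(f"threshold {site}/{cls}={value} outside [0, 1]")
        for site, value in self.rain_filter.items():
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"rain filter {site}={value} outside [0, 1]")

    def get(self, site: str, cls: str) -> float:
        if site not in self.thresholds:
            raise KeyError(f"site {site!r} has no thresholds configured")
        table = self.thresholds[site]
        if cls not in table:
            raise KeyError(f"site {site!r} has no threshold for class {cls!r}")
        return table[cls]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ThresholdTable":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(
            thresholds=data["thresholds"],
            rain_filter=data.get("rain_filter", {}) or {},
        )

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(
                {"thresholds": self.thresholds, "rain_filter": self.rain_filter}, fh
            )


def classify_archive(
    model,
    mel_matrices: np.ndarray,
    meta: pd.DataFrame,
    thresholds: ThresholdTable,
    classes: tuple[str, ...] = TARGET_CLASSES,
) -> pd.DataFrame:
    """Score an archive of segments and apply per-site decision thresholds.

    ``meta`` must align row-wise with ``mel_matrices`` and carry
    ``segment_id``, ``site`` and ``start_time_iso``.  Every site present in
    ``meta`` must be configured in ``thresholds`` (checked before any
    computation).  Returns one detection record per segment, in input order.
    """
    required = {"segment_id", "site", "start_time_iso"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"meta is missing columns: {sorted(missing)}")
    if len(meta) != len(mel_matrices):
        raise ValueError("meta and mel_matrices must align row-wise")
    for site in meta["site"].unique():
        for cls in ("click", "boat"):
            thresholds.get(site, cls)  # raises before any scoring work

    scores = model.predict_proba(mel_matrices)  # (n, 16, n_classes)
    q75 = q75_scores(scores)
    return detections_from_scores(q75, meta, thresholds, classes)


def detections_from_scores(
    q75: np.ndarray,
    meta: pd.DataFrame,
    thresholds: ThresholdTable,
    classes: tuple[str, ...] = TARGET_CLASSES,
) -> pd.DataFrame:
    """Build the detections table from precomputed Q75 scores.

    Click and boat flags use the site's decision thresholds.  The rain flag
    uses the site's explicit rain threshold when configured, falling back to
    the rain-filter threshold, else stays False.
    """
    records = []
    for i, row in enumerate(meta.itertuples(index=False)):
        rec = {
            "segment_id": row.segment_id,
            "site": row.site,
            "start_time_iso": row.start_time_iso,
            "rain_attributed": False,
        }
        site_table = thresholds.thresholds.get(row.site, {})
        for c, cls in enumerate(classes):
            rec[f"q75_{cls}"] = float(q75[i, c])
            if cls in site_table:
                thr = site_table[cls]
            elif cls == "rain":
                thr = thresholds.rain_filter.get(row.site)
            else:
                thr = thresholds.get(row.site, cls)  # raises: required class
            rec[f"flag_{cls}"] = bool(thr is not None and q75[i, c] >= thr)
        records.append(rec)
    return pd.DataFrame(records)[DETECTIONS_COLUMNS]


def apply_rain_filter(
    records: pd.DataFrame, thresholds: ThresholdTable
) -> pd.DataFrame:
    """Attribute click/rain double-positives to rain.

    For every site with a rain-filter threshold, any segment whose click
    flag is set and whose rain Q75 is >= that threshold has its click flag
    cleared and ``rain_attributed`` set.  Boat flags are untouched.  Sites
    without a configured rain filter are skipped (logged via a warning).
    """
    out = records.copy()
    for site in out["site"].unique():
        rft = thresholds.rain_filter.get(site)
        if rft is None:
            warnings.warn(
                f"site {site!r} has no rain-filter threshold; filter skipped",
                stacklevel=2,
            )
            continue
        mask = (
            (out["site"] == site)
            & out["flag_click"]
            & (out["q75_rain"] >= rft)
        )
        out.loc[mask, "flag_click"] = False
        out.loc[mask, "rain_attributed"] = True
    return out


def sample_for_review(
    records: pd.DataFrame,
    class_name: str,
    threshold: float,
    n: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Uniform sample of positively classified segments for manual review.

    Draws ``n`` records without replacement from those whose Q75 for
    ``class_name`` is >= ``threshold``; if fewer positives exist, all are
    returned with a warning.  Reproducible via ``seed``.
    """
    positives = records[records[f"q75_{class_name}"] >= threshold]
    if len(positives) == 0:
        raise ValueError(f"no {class_name} positives above {threshold}")
    if len(positives) <= n:
        if len(positives) < n:
            warnings.warn(
                f"only {len(positives)} positives available for the requested "
                f"{n}; returning all",
                stacklevel=2,
            )
        return positives.reset_index(drop=True)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(positives), size=n, replace=False)
    return positives.iloc[np.sort(idx)].reset_index(drop=True)


def export_review_batch(
    batch: pd.DataFrame,
    out_dir: str | Path,
    audio_lookup=None,
    mel_lookup=None,
) -> Path:
    """Write review artifacts: per-segment WAV snippet and spectrogram PNG.

    ``audio_lookup`` and ``mel_lookup`` map a segment_id to the 5-s samples
    and its mel matrix; either may be omitted.  Returns the batch directory
    containing a ``review.csv`` verdict sheet to be filled in manually.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if audio_lookup is not None or mel_lookup is not None:
        from botopam.audio_io import WORKING_RATE_HZ, Waveform, write_wav

        for seg_id in batch["segment_id"]:
            safe = str(seg_id).replace(":", "_").replace("/", "_")
            if audio_lookup is not None:
                write_wav(
                    out_dir / f"{safe}.wav",
                    Waveform(samples=audio_lookup(seg_id), rate_hz=WORKING_RATE_HZ),
                )
            if mel_lookup is not None:
                import matplotlib

                matplotlib.use("Agg")
                import matplotlib.pyplot as plt

                fig, ax = plt.subplots(figsize=(6, 3))
                ax.imshow(
                    np.asarray(mel_lookup(seg_id)).T,
                    origin="lower",
                    aspect="auto",
                    cmap="viridis",
                )
                ax.set_xlabel("time frame")
                ax.set_ylabel("Mel band")
                fig.savefig(out_dir / f"{safe}.png", dpi=80)
                plt.close(fig)
    sheet = batch[["segment_id", "site", "start_time_iso"]].copy()
    sheet["verdict"] = ""
    sheet.to_csv(out_dir / "review.csv", index=False)
    return out_dir


def merge_corrections(
    train_manifest: pd.DataFrame, reviewed: pd.DataFrame
) -> pd.DataFrame:
    """Fold human verdicts back into the training manifest.

    ``reviewed`` needs ``segment_id`` and ``verdict`` (semicolon-separated
    class names; empty string = background).  Records lacking a verdict are
    skipped with a warning; segment_ids already in the manifest are rejected
    as duplicates, making a double merge a no-op.
    """
    if "segment_id" not in reviewed.columns:
        raise ValueError("reviewed batch must carry segment_id")
    existing = set(train_manifest["segment_id"])
    new_rows = []
    for row in reviewed.itertuples(index=False):
        verdict = getattr(row, "verdict", None)
        if verdict is None or (isinstance(verdict, float) and np.isnan(verdict)):
            warnings.warn(
                f"segment {row.segment_id} has no verdict; skipped", stacklevel=2
            )
            continue
        if row.segment_id in existing:
            continue
        labels = ";".join(sorted(v for v in str(verdict).split(";") if v))
        new_rows.append({"segment_id": row.segment_id, "labels": labels})
        existing.add(row.segment_id)
    if not new_rows:
        return train_manifest.copy()
    return pd.concat(
        [train_manifest, pd.DataFrame(new_rows)], ignore_index=True
    )


def write_detections_csv(path: str | Path, records: pd.DataFrame) -> None:
    records[DETECTIONS_COLUMNS].to_csv(path, index=False)


def read_detections_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("flag_click", "flag_boat", "flag_rain", "rain_attributed"):
        df[col] = df[col].astype(bool)
    return df
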