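"""Intensity normalization, slice filtering, and patient-disjoint splits.

Conventions: "tissue" means strictly nonzero pixels in the
pre-normalization volume (brain-extracted background is exactly zero);
the tissue filter boundary is inclusive (a slice with exactly the
threshold fraction of tissue is kept).  Train size uses the floor rule;
all randomness is driven by an explicit seed on a sorted subject list so
splits are reproducible.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .exceptions import ConfigurationError, DegenerateInputError

__all__ = [
    "DatasetSplit",
    "normalize_intensity",
    "select_slices",
    "split_paired",
    "split_unpaired",
    "holdout_fid_subset",
    "save_split",
    "load_split",
]


@dataclass
class DatasetSplit:
    """Patient-disjoint train/test split with optional FID holdout and
    unpaired domain assignment."""

    train_ids: set[str] = field(default_factory=set)
    test_ids: set[str] = field(default_factory=set)
    fid_holdout: list[tuple[str, int]] = field(default_factory=list)
    unpaired_domains: tuple[set[str], set[str]] | None = None

    def validate(self) -> None:
        if self.train_ids & self.test_ids:
            raise ConfigurationError("train and test subjects overlap")
        holdout_subjects = {sid for sid, _ in self.fid_holdout}
        if not holdout_subjects <= self.train_ids:
            raise ConfigurationError("FID holdout subjects must come from the training set")
        if self.unpaired_domains is not None:
            a, b = self.unpaired_domains
            if a & b:
                raise ConfigurationError("unpaired domains must be disjoint")
            if not (a | b) <= self.train_ids:
                raise ConfigurationError("unpaired domains must be training subjects")


def normalize_intensity(volume: np.ndarray) -> np.ndarray:
    """Affine min-max map of a volume onto [-1, 1].

    Applied per volume (not per slice) so inter-slice contrast is
    preserved.  Raises :class:`DegenerateInputError` on a constant volume.
    """
    volume = np.asarray(volume, dtype=float)
    vmin, vmax = float(volume.min()), float(volume.max())
    if vmax == vmin:
        raise DegenerateInputError("cannot min-max normalize a constant volume")
    return 2.0 * (volume - vmin) / (vmax - vmin) - 1.0


def select_slices(volume: np.ndarray, threshold: float = 0.15) -> list[int]:
    """Indices of slices whose tissue fraction is at least ``threshold``.

    Tissue fraction = nonzero pixels / total pixels, computed on the
    pre-normalization volume where background is exactly zero.  The slice
    axis is the last axis.
    """
    if not 0 < threshold < 1:
        raise ConfigurationError("threshold must lie in (0, 1)")
    volume = np.asarray(volume)
    fractions = np.count_nonzero(volume, axis=(0, 1)) / (volume.shape[0] * volume.shape[1])
    return [int(i) for i in np.nonzero(fractions >= threshold)[0]]


def split_paired(
    subject_ids: Sequence[str], train_fraction: float = 0.8, seed: int = 0
) -> DatasetSplit:
    """Patient-disjoint 80/20-style split; train size = floor(fraction * N)."""
    if not 0 < train_fraction < 1:
        raise ConfigurationError("train_fraction must lie in (0, 1)")
    ids = sorted(str(s) for s in subject_ids)
    if len(ids) != len(set(ids)):
        raise ConfigurationError("subject_ids must be unique")
    if len(ids) < 2:
        raise ConfigurationError("need at least 2 subjects to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = int(np.floor(train_fraction * len(ids)))
    train = {ids[i] for i in order[:n_train]}
    test = {ids[i] for i in order[n_train:]}
    split = DatasetSplit(train_ids=train, test_ids=test)
    split.validate()
    return split


def split_unpaired(split: DatasetSplit, seed: int = 0) -> DatasetSplit:
    """Partition the training subjects into two disjoint halves, so
    source-domain and target-domain training images come from different
    patients.  Half sizes differ by at most one."""
    train = sorted(split.train_ids)
    if len(train) < 2:
        raise ConfigurationError("need at least 2 training subjects for unpaired domains")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(train))
    half = (len(train) + 1) // 2
    source_dom = {train[i] for i in order[:half]}
    target_dom = {train[i] for i in order[half:]}
    out = DatasetSplit(
        train_ids=set(split.train_ids),
        test_ids=set(split.test_ids),
        fid_holdout=list(split.fid_holdout),
        unpaired_domains=(source_dom, target_dom),
    )
    out.validate()
    return out


def holdout_fid_subset(
    split: DatasetSplit,
    eligible_slices: Mapping[str, Sequence[int]],
    n_images: int = 256,
    n_subjects: int = 9,
    seed: int = 0,
) -> DatasetSplit:
    """Hold out ``n_images`` (subject, slice) pairs from exactly
    ``n_subjects`` training subjects for in-training FID computation.

    ``eligible_slices`` maps training subject ids to their tissue-filtered
    slice indices.  Every chosen subject contributes at least one slice.
    The held-out slices are meant to be excluded from the gradient-update
    stream entirely.
    """
    if n_images == 0:
        return DatasetSplit(
            train_ids=set(split.train_ids),
            test_ids=set(split.test_ids),
            fid_holdout=[],
            unpaired_domains=split.unpaired_domains,
        )
    candidates = sorted(set(split.train_ids) & set(eligible_slices))
    if len(candidates) < n_subjects:
        raise ConfigurationError(
            f"need {n_subjects} training subjects with eligible slices, have {len(candidates)}"
        )
    rng = np.random.default_rng(seed)
    chosen = [candidates[i] for i in rng.permutation(len(candidates))[:n_subjects]]
    pools = {sid: list(eligible_slices[sid]) for sid in chosen}
    total = sum(len(v) for v in pools.values())
    if total < n_images:
        raise ConfigurationError(
            f"chosen subjects contribute {total} eligible slices, need {n_images}"
        )
    # one slice from each subject first so exactly n_subjects are represented
    holdout: list[tuple[str, int]] = []
    remaining: list[tuple[str, int]] = []
    for sid in chosen:
        idx = rng.integers(len(pools[sid]))
        holdout.append((sid, int(pools[sid][idx])))
        rest = [s for j, s in enumerate(pools[sid]) if j != idx]
        remaining.extend((sid, int(s)) for s in rest)
    need = n_images - len(holdout)
    if need < 0:
        raise ConfigurationError("n_images must be >= n_subjects")
    if need:
        pick = rng.permutation(len(remaining))[:need]
        holdout.extend(remaining[i] for i in pick)
    holdout.sort()
    out = DatasetSplit(
        train_ids=set(split.train_ids),
        test_ids=set(split.test_ids),
        fid_holdout=holdout,
        unpaired_domains=split.unpaired_domains,
    )
    out.validate()
    return out


def save_split(split: DatasetSplit, path: str | Path) -> None:
    payload = {
        "train_ids": sorted(split.train_ids),
        "test_ids": sorted(split.test_ids),
        "fid_holdout": [[sid, int(idx)] for sid, idx in split.fid_holdout],
        "unpaired_domains": (
            [sorted(split.unpaired_domains[0]), sorted(split.unpaired_domains[1])]
            if split.unpaired_domains
            else None
        ),
    }
    Path(path).write_text(json.dumps(payload, indent=2))


def load_split(path: str | Path) -> DatasetSplit:
    data = json.loads(Path(path).read_text())
    domains = data.get("unpaired_domains")
    split = DatasetSplit(
        train_ids=set(data["train_ids"]),
        test_ids=set(data["test_ids"]),
        fid_holdout=[(sid, int(idx)) for sid, idx in data["fid_holdout"]],
        unpaired_domains=(set(domains[0]), set(domains[1])) if domains else None,
    )
    split.validate()
    return split
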