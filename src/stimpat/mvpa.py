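"""ROI-based multivariate pattern analysis (MVPA).

Two complementary analyses operate on a :class:`PatternDataset` (samples x
voxels with condition/run labels, one dataset per participant per ROI):

* **split-half correlational analysis** — data are mean-centred per voxel
  within each run, randomly split into two halves stratified by condition,
  condition averages of one half are correlated with those of the other,
  and the procedure is repeated over many random splits (100 by default)
  with Fisher-z averaging of the resulting correlations;
* **pairwise nu-SVM decoding** — data are mean-centred across voxels per
  (run, condition) group, and for every unordered pair of conditions a
  linear nu-SVM is trained on roughly 75% of the samples and tested on the
  per-condition average of the held-out 25%, again over 100 random splits.

A synthetic pattern simulator (`simulate_patterns`) produces fMRI-like
data — condition templates plus run-level and sample-level Gaussian noise
at controllable SNR — so both analyses are testable end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.svm import NuSVC

__all__ = [
    "PatternDataset",
    "SimulationSpec",
    "normalize_correlation",
    "normalize_svm",
    "split_half",
    "train_test_split",
    "correlational_analysis",
    "pairwise_svm_decode",
    "simulate_patterns",
    "read_dataset_csv",
    "write_dataset_csv",
]

DEFAULT_N_ITER = 100
DEFAULT_TRAIN_FRAC = 0.75
DEFAULT_NU = 0.5


@dataclass(frozen=True)
class PatternDataset:
    """Samples x voxels pattern matrix with condition/run/subject/ROI labels."""

    data: np.ndarray          # (n_samples, n_voxels)
    condition: np.ndarray     # label per sample
    run: np.ndarray           # int per sample
    subject: str = "subj01"
    roi: str = "roi"

    def __post_init__(self):
        data = np.asarray(self.data, dtype=float)
        cond = np.asarray(self.condition)
        run = np.asarray(self.run, dtype=int)
        if data.ndim != 2:
            raise ValueError("data must be a 2D samples x voxels matrix")
        if data.shape[1] < 2:
            raise ValueError("need at least 2 voxels")
        if len(cond) != data.shape[0] or len(run) != data.shape[0]:
            raise ValueError("label length must equal the number of samples")
        if len(np.unique(cond)) < 2:
            raise ValueError("need at least 2 distinct conditions")
        object.__setattr__(self, "data", data)
        object.__setattr__(self, "condition", cond)
        object.__setattr__(self, "run", run)

    @property
    def n_samples(self) -> int:
        return self.data.shape[0]

    @property
    def n_voxels(self) -> int:
        return self.data.shape[1]

    @property
    def conditions(self) -> np.ndarray:
        return np.unique(self.condition)

    def check_runs(self) -> None:
        """Verify that every run contains every condition (analysis entry
        requirement; subsets produced by splitting need not satisfy it)."""
        conds = set(self.conditions.tolist())
        for r in np.unique(self.run):
            present = set(np.unique(self.condition[self.run == r]).tolist())
            if present != conds:
                missing = conds - present
                raise ValueError(
                    f"run {r} is missing condition(s): {sorted(missing)}")

    def subset(self, idx) -> "PatternDataset":
        idx = np.asarray(idx)
        return replace(self, data=self.data[idx],
                       condition=self.condition[idx], run=self.run[idx])


# --------------------------------------------------------------------------
# normalization
# --------------------------------------------------------------------------

def normalize_correlation(ds: PatternDataset) -> PatternDataset:
    """Centre each voxel within each run (subtract its mean over the run's
    samples).  This removes run-level offsets before correlating patterns."""
    data = ds.data.copy()
    for r in np.unique(ds.run):
        m = ds.run == r
        data[m] -= data[m].mean(axis=0, keepdims=True)
    return replace(ds, data=data)


def normalize_svm(ds: PatternDataset) -> PatternDataset:
    """Centre each (run, condition) group across voxels: one scalar mean per
    group, subtracted from that group's samples."""
    data = ds.data.copy()
    for r in np.unique(ds.run):
        for c in np.unique(ds.condition):
            m = (ds.run == r) & (ds.condition == c)
            if m.any():
                data[m] -= data[m].mean()
    return replace(ds, data=data)


# --------------------------------------------------------------------------
# splitting
# --------------------------------------------------------------------------

def split_half(ds: PatternDataset, rng: np.random.Generator,
               unit: str = "sample"):
    """Random half split, stratified by condition.

    With ``unit="sample"`` (default) each condition's samples are
    partitioned as evenly as possible; with an odd count the extra sample
    goes to a uniformly random half.  With ``unit="run"`` whole runs are
    assigned to halves, which avoids any leakage of run-level noise between
    the halves.  The two halves are disjoint and exhaustive.
    """
    if unit == "run":
        runs = np.unique(ds.run)
        if len(runs) < 2:
            raise ValueError("run-level split needs at least 2 runs")
        perm = rng.permutation(runs)
        half = len(perm) // 2
        if len(perm) % 2 == 1 and rng.integers(2) == 1:
            half += 1
        in_a = np.isin(ds.run, perm[:half])
        return ds.subset(np.flatnonzero(in_a)), ds.subset(np.flatnonzero(~in_a))
    if unit != "sample":
        raise ValueError("unit must be 'sample' or 'run'")
    idx_a, idx_b = [], []
    for c in ds.conditions:
        idx = np.flatnonzero(ds.condition == c)
        if len(idx) < 2:
            raise ValueError(
                f"condition {c!r} has fewer than 2 samples; cannot split")
        perm = rng.permutation(idx)
        half = len(perm) // 2
        if len(perm) % 2 == 1 and rng.integers(2) == 1:
            half += 1  # odd leftover to a random half
        idx_a.extend(perm[:half])
        idx_b.extend(perm[half:])
    return ds.subset(np.sort(idx_a)), ds.subset(np.sort(idx_b))


def train_test_split(ds: PatternDataset,
                     train_frac: float = DEFAULT_TRAIN_FRAC,
                     rng: np.random.Generator | None = None,
                     unit: str = "sample"):
    """Random train/test split per condition at `train_frac` (default 0.75).

    With ``unit="sample"`` each condition contributes
    ``round(train_frac * count)`` samples to the training set, clamped so
    both sides get at least one sample.  With ``unit="run"`` whole runs are
    assigned (``round(train_frac * n_runs)`` to training, clamped likewise),
    which keeps run-level noise from leaking between train and test.
    """
    if not 0.0 < train_frac < 1.0:
        raise ValueError("train_frac must be in (0, 1)")
    if rng is None:
        rng = np.random.default_rng()
    if unit == "run":
        runs = np.unique(ds.run)
        if len(runs) < 2:
            raise ValueError("run-level split needs at least 2 runs")
        n_train = min(max(int(round(train_frac * len(runs))), 1),
                      len(runs) - 1)
        perm = rng.permutation(runs)
        in_train = np.isin(ds.run, perm[:n_train])
        return (ds.subset(np.flatnonzero(in_train)),
                ds.subset(np.flatnonzero(~in_train)))
    if unit != "sample":
        raise ValueError("unit must be 'sample' or 'run'")
    idx_tr, idx_te = [], []
    for c in ds.conditions:
        idx = np.flatnonzero(ds.condition == c)
        if len(idx) < 2:
            raise ValueError(
                f"condition {c!r} has fewer than 2 samples; cannot split")
        n_train = int(round(train_frac * len(idx)))
        n_train = min(max(n_train, 1), len(idx) - 1)
        perm = rng.permutation(idx)
        idx_tr.extend(perm[:n_train])
        idx_te.extend(perm[n_train:])
    return ds.subset(np.sort(idx_tr)), ds.subset(np.sort(idx_te))


# --------------------------------------------------------------------------
# analyses
# --------------------------------------------------------------------------

def _condition_means(ds: PatternDataset) -> dict:
    return {c: ds.data[ds.condition == c].mean(axis=0) for c in ds.conditions}


def _corr(a: np.ndarray, b: np.ndarray) -> float:
    sa, sb = a.std(), b.std()
    if sa == 0.0 or sb == 0.0:
        raise ValueError("correlation undefined for a zero-variance pattern")
    return float(np.corrcoef(a, b)[0, 1])


# clip before arctanh so r = +-1 survives Fisher averaging as exactly +-1
_FISHER_CLIP = 1.0 - 1e-15


def correlational_analysis(ds: PatternDataset,
                           n_iter: int = DEFAULT_N_ITER,
                           seed: int | None = None,
                           fisher: bool = True,
                           split_unit: str = "sample") -> pd.DataFrame:
    """Split-half correlational MVPA.

    Normalises per run per voxel, then for each of `n_iter` random
    stratified half splits correlates half-A condition averages with half-B
    condition averages for every ordered condition pair, symmetrises by
    averaging (i,j) with (j,i), and averages across iterations (Fisher-z by
    default).  Returns a long-format table with one row per unordered
    condition pair, including i = i (split-half reliability).
    """
    ds.check_runs()
    rng = np.random.default_rng(seed)
    dsn = normalize_correlation(ds)
    conds = list(dsn.conditions)
    k = len(conds)
    acc = np.zeros((k, k, n_iter))
    for it in range(n_iter):
        half_a, half_b = split_half(dsn, rng, unit=split_unit)
        mean_a = _condition_means(half_a)
        mean_b = _condition_means(half_b)
        for i, ci in enumerate(conds):
            for j, cj in enumerate(conds):
                acc[i, j, it] = _corr(mean_a[ci], mean_b[cj])
    sym = (acc + acc.transpose(1, 0, 2)) / 2.0
    if fisher:
        z = np.arctanh(np.clip(sym, -_FISHER_CLIP, _FISHER_CLIP))
        avg = np.tanh(z.mean(axis=2))
    else:
        avg = sym.mean(axis=2)

    records = [
        {"subject": ds.subject, "roi": ds.roi,
         "condition_a": conds[i], "condition_b": conds[j],
         "statistic": "correlation", "value": avg[i, j]}
        for i in range(k) for j in range(i, k)
    ]
    out = pd.DataFrame.from_records(records)
    out.attrs["metadata"] = {
        "analysis": "splithalf_correlation", "n_iter": n_iter,
        "seed": seed, "fisher": fisher, "split_unit": split_unit,
    }
    return out


def pairwise_svm_decode(ds: PatternDataset,
                        n_iter: int = DEFAULT_N_ITER,
                        nu: float = DEFAULT_NU,
                        train_frac: float = DEFAULT_TRAIN_FRAC,
                        seed: int | None = None,
                        split_unit: str = "sample") -> pd.DataFrame:
    """Pairwise linear nu-SVM decoding.

    Normalises across voxels per (run, condition), then for every unordered
    condition pair runs `n_iter` random 75/25 train/test splits.  Each
    iteration fits a linear nu-SVM on the training samples, averages the
    held-out test samples into one pattern per condition, and classifies
    both averages, giving an iteration accuracy in {0, 0.5, 1}.  The table
    reports the mean accuracy over iterations per pair.
    """
    ds.check_runs()
    rng = np.random.default_rng(seed)
    dsn = normalize_svm(ds)
    conds = list(dsn.conditions)
    records = []
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            ci, cj = conds[i], conds[j]
            pair = dsn.subset(np.flatnonzero(
                (dsn.condition == ci) | (dsn.condition == cj)))
            accs = np.empty(n_iter)
            for it in range(n_iter):
                train, test = train_test_split(pair, train_frac, rng,
                                               unit=split_unit)
                clf = NuSVC(nu=nu, kernel="linear")
                try:
                    clf.fit(train.data, train.condition.astype(str))
                except ValueError as exc:
                    raise ValueError(
                        f"SVM fit failed for pair ({ci}, {cj}): {exc}") from exc
                test_means = _condition_means(test)
                pred = clf.predict(np.stack([test_means[ci], test_means[cj]]))
                accs[it] = np.mean(pred == np.array([str(ci), str(cj)]))
            records.append({
                "subject": ds.subject, "roi": ds.roi,
                "condition_a": ci, "condition_b": cj,
                "statistic": "accuracy", "value": accs.mean(),
            })
    out = pd.DataFrame.from_records(records)
    out.attrs["metadata"] = {
        "analysis": "pairwise_svm", "n_iter": n_iter, "nu": nu,
        "train_frac": train_frac, "seed": seed, "split_unit": split_unit,
    }
    return out


# --------------------------------------------------------------------------
# simulation
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulationSpec:
    """Parameters of the synthetic fMRI-like pattern generator.

    Each condition gets a fixed voxel template drawn from
    ``Normal(0, signal_sd)``.  Every sample is its condition's template plus
    a run-level offset (``Normal(0, run_noise_sd)`` per voxel, shared by all
    samples of the run) plus independent ``Normal(0, sample_noise_sd)``
    noise.
    """

    n_conditions: int = 4
    n_runs: int = 4
    samples_per_condition_per_run: int = 2
    n_voxels: int = 50
    signal_sd: float = 1.0
    run_noise_sd: float = 0.5
    sample_noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        counts = (self.n_conditions, self.n_runs,
                  self.samples_per_condition_per_run, self.n_voxels)
        if any(c < 1 for c in counts):
            raise ValueError("all counts must be >= 1")
        if min(self.signal_sd, self.run_noise_sd, self.sample_noise_sd) < 0:
            raise ValueError("noise standard deviations must be >= 0")


def simulate_patterns(spec: SimulationSpec,
                      subject: str = "sim01",
                      roi: str = "sim_roi") -> PatternDataset:
    """Generate a deterministic synthetic :class:`PatternDataset` from `spec`."""
    rng = np.random.default_rng(spec.seed)
    templates = rng.normal(0.0, spec.signal_sd,
                           (spec.n_conditions, spec.n_voxels))
    rows, conds, runs = [], [], []
    for r in range(spec.n_runs):
        offset = rng.normal(0.0, spec.run_noise_sd, spec.n_voxels)
        for c in range(spec.n_conditions):
            for _ in range(spec.samples_per_condition_per_run):
                noise = rng.normal(0.0, spec.sample_noise_sd, spec.n_voxels)
                rows.append(templates[c] + offset + noise)
                conds.append(f"cond{c:02d}")
                runs.append(r)
    return PatternDataset(np.stack(rows), np.array(conds), np.array(runs),
                          subject=subject, roi=roi)


# --------------------------------------------------------------------------
# CSV dataset I/O (matrix CSV + sidecar labels CSV)
# --------------------------------------------------------------------------

def write_dataset_csv(ds: PatternDataset, data_path, labels_path) -> None:
    """Write a dataset as a samples x voxels matrix CSV (header = voxel ids)
    plus a sidecar labels CSV (sample_id, condition, run, subject, roi)."""
    n = ds.n_samples
    voxels = [f"v{j:04d}" for j in range(ds.n_voxels)]
    pd.DataFrame(ds.data, columns=voxels).to_csv(data_path, index=False)
    pd.DataFrame({
        "sample_id": np.arange(n),
        "condition": ds.condition,
        "run": ds.run,
        "subject": ds.subject,
        "roi": ds.roi,
    }).to_csv(labels_path, index=False)


def read_dataset_csv(data_path, labels_path) -> PatternDataset:
    """Inverse of :func:`write_dataset_csv`."""
    data = pd.read_csv(data_path).to_numpy(dtype=float)
    labels = pd.read_csv(labels_path)
    for col in ("condition", "run"):
        if col not in labels.columns:
            raise ValueError(f"labels CSV is missing required column {col!r}")
    subject = str(labels["subject"].iloc[0]) if "subject" in labels else "subj01"
    roi = str(labels["roi"].iloc[0]) if "roi" in labels else "roi"
    return PatternDataset(data, labels["condition"].to_numpy(),
                          labels["run"].to_numpy(), subject=subject, roi=roi)
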