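"""Learned validation of search results.

Per run — never transferred across runs — two small models are trained on
the run's own target/decoy matches:

* a retention-time regressor over a 63-dimensional composition encoding of
  the peptide (20 whole-sequence residue counts, 20 counts over the first
  two residues, 20 over the last two, the C-terminal residue index, the
  length, and the modified neutral mass);
* a discriminant network over the match features (scores, matched-ion
  statistics, precursor charge, mass difference, modification and cleavage
  counts, and the RT prediction error), trained to separate
  confidently-identified target precursors (q <= 1% by hyperscore) from
  decoy matches.

Records are then ranked by the discriminant score d and q-values are
computed by target-decoy competition at the PSM, peptide, and protein
levels; reports keep targets at q <= 1%.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import Ridge
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.preprocessing import StandardScaler

from .constants import AA_INDEX, ALPHABET
from .proteome import ModifiedPeptide
from .search import PSMRecord

logger = logging.getLogger(__name__)

__all__ = [
    "encode_rt_features",
    "RTModel",
    "train_rt_model",
    "assemble_training_set",
    "DiscriminantModel",
    "train_discriminant",
    "compute_qvalues",
    "final_report",
    "run_validation",
    "ValidationError",
]

RT_FEATURE_DIM = 63

#: minimum confident peptides for the neural RT model; below this a linear
#: model is fitted; below RT_MIN_PEPTIDES the RT feature is disabled.
RT_MIN_NEURAL = 200
RT_MIN_PEPTIDES = 20


class ValidationError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Retention-time model


def encode_rt_features(peptide: ModifiedPeptide | str, position_deltas=None) -> np.ndarray:
    """63-dim composition encoding of a peptide.

    Layout: [0:20] whole-sequence residue counts, [20:40] counts over the
    first two residues, [40:60] counts over the last two residues, [60]
    C-terminal residue index (alphabetical order), [61] length, [62]
    neutral mass in Da including modification deltas. Composition counts
    ignore modification state; only the mass reflects it.
    """
    if isinstance(peptide, ModifiedPeptide):
        seq = peptide.sequence
        mass = peptide.neutral_mass
    else:
        from .proteome import peptide_mass

        seq = peptide
        if any(aa not in AA_INDEX for aa in seq):
            raise ValueError(f"non-canonical residue in {seq!r}")
        mass = peptide_mass(seq, position_deltas)
    if len(seq) < 2:
        raise ValueError("peptide must have length >= 2")
    v = np.zeros(RT_FEATURE_DIM)
    try:
        for aa in seq:
            v[AA_INDEX[aa]] += 1
        for aa in seq[:2]:
            v[20 + AA_INDEX[aa]] += 1
        for aa in seq[-2:]:
            v[40 + AA_INDEX[aa]] += 1
        v[60] = AA_INDEX[seq[-1]]
    except KeyError as e:
        raise ValueError(f"non-canonical residue {e} in {seq!r}") from None
    v[61] = len(seq)
    v[62] = mass
    return v


def _rt_matrix(peptides: Sequence[ModifiedPeptide | str]) -> np.ndarray:
    return np.vstack([encode_rt_features(p) for p in peptides])


@dataclass
class RTModel:
    """Retention-time predictor (seconds) over the 63-dim encoding.

    ``kind`` is "neural", "linear", or "disabled". Predictions are
    deterministic given the training seed.
    """

    kind: str
    seed: int
    scaler: StandardScaler | None = None
    model: object | None = None
    rt_min: float = 0.0
    rt_span: float = 1.0
    train_loss: float = float("nan")
    val_loss: float = float("nan")

    @property
    def enabled(self) -> bool:
        return self.kind != "disabled"

    def predict(self, peptides: Sequence[ModifiedPeptide | str]) -> np.ndarray:
        if not self.enabled:
            return np.zeros(len(peptides))
        X = self.scaler.transform(_rt_matrix(peptides))
        y = np.asarray(self.model.predict(X), dtype=np.float64)
        return y * self.rt_span + self.rt_min


def train_rt_model(
    peptides: Sequence[ModifiedPeptide | str],
    retention_times: Sequence[float],
    seed: int = 42,
) -> RTModel:
    """Fit the retention-time model from scratch on this run's peptides.

    >= 200 peptides: multilayer perceptron (two 64-unit ReLU layers,
    L-BFGS). 20..199: ridge regression on the same features. < 20: the
    model is disabled and downstream RT-error features are zeroed.
    Train/validation losses are reported on a seeded 90/10 split.
    """
    rts = np.asarray(retention_times, dtype=np.float64)
    n = len(peptides)
    if n != rts.size:
        raise ValueError("peptides and retention times must align")
    if n < RT_MIN_PEPTIDES:
        logger.warning("only %d confident peptides: RT model disabled", n)
        return RTModel(kind="disabled", seed=seed)
    X = _rt_matrix(peptides)
    scaler = StandardScaler().fit(X)
    Xs = scaler.transform(X)
    rt_min = float(rts.min())
    rt_span = float(rts.max() - rt_min) or 1.0
    y = (rts - rt_min) / rt_span
    if n >= RT_MIN_NEURAL:
        kind = "neural"
        # full-batch L-BFGS: converges far better than SGD/Adam at these
        # training-set sizes (hundreds to a few thousand peptides)
        model = MLPRegressor(
            hidden_layer_sizes=(64, 64),
            activation="relu",
            solver="lbfgs",
            random_state=seed,
            max_iter=1500,
        )
    else:
        logger.warning("only %d confident peptides: linear RT fallback", n)
        kind = "linear"
        model = Ridge(alpha=1.0, random_state=seed)
    model.fit(Xs, y)
    # report losses on a deterministic 90/10 split
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    cut = max(1, n // 10)
    val, train = perm[:cut], perm[cut:]
    pred = np.asarray(model.predict(Xs))
    mse = lambda idx: float(np.mean((pred[idx] - y[idx]) ** 2)) * rt_span**2
    rt = RTModel(
        kind=kind,
        seed=seed,
        scaler=scaler,
        model=model,
        rt_min=rt_min,
        rt_span=rt_span,
        train_loss=mse(train),
        val_loss=mse(val),
    )
    logger.info(
        "RT model (%s): train MSE %.1f s^2, val MSE %.1f s^2",
        kind, rt.train_loss, rt.val_loss,
    )
    return rt


# ---------------------------------------------------------------------------
# q-values


def compute_qvalues(
    scores,
    is_decoy,
    keys: Sequence | None = None,
    level: str = "psm",
) -> pd.DataFrame:
    """Target-decoy q-values from discriminant scores.

    Records are sorted by score descending; FDR at rank i is
    (# decoys in top i) / max(1, # targets in top i); the q-value is the
    running minimum of FDR from the bottom up, and records tied on score
    share the q of the lowest-ranked member of the tie.

    For ``level`` "peptide" or "protein", records are first collapsed to
    the best score per ``key`` (a decoy key stays a decoy only if every
    record under it is a decoy).

    Returns a DataFrame sorted by score descending with columns
    ``key, score, is_decoy, q``.
    """
    scores = np.asarray(scores, dtype=np.float64)
    is_decoy = np.asarray(is_decoy, dtype=bool)
    if scores.size == 0:
        return pd.DataFrame(columns=["key", "score", "is_decoy", "q"])
    if keys is None:
        keys = np.arange(scores.size)
    df = pd.DataFrame({"key": list(keys), "score": scores, "is_decoy": is_decoy})
    if level != "psm":
        df = (
            df.groupby("key", sort=False)
            .agg(score=("score", "max"), is_decoy=("is_decoy", "all"))
            .reset_index()
        )
    df = df.sort_values(
        ["score", "is_decoy", "key"], ascending=[False, True, True], kind="stable"
    ).reset_index(drop=True)
    dec = df["is_decoy"].to_numpy()
    n_dec = np.cumsum(dec)
    n_tgt = np.cumsum(~dec)
    fdr = n_dec / np.maximum(1, n_tgt)
    q = np.minimum.accumulate(fdr[::-1])[::-1]
    # ties on score share the q of the lowest-ranked member
    q = pd.Series(q).groupby(df["score"], sort=False).transform("max").to_numpy()
    df["q"] = np.clip(q, 0.0, 1.0)
    return df


# ---------------------------------------------------------------------------
# Training-set assembly and the discriminant


def _precursor_best(psms: Sequence[PSMRecord]) -> list[PSMRecord]:
    """Best PSM per precursor = (peptide key incl. modifications, charge)."""
    best: dict[tuple[str, int], PSMRecord] = {}
    for p in psms:
        k = (p.peptide.key(), p.precursor_charge)
        cur = best.get(k)
        if cur is None or (p.hyperscore, p.xcorr) > (cur.hyperscore, cur.xcorr):
            best[k] = p
    return list(best.values())


def assemble_training_set(
    psms: Sequence[PSMRecord], fdr: float = 0.01
) -> tuple[list[PSMRecord], list[PSMRecord]]:
    """Positive/negative PSMs for discriminant training.

    Positives: target precursors (best PSM per peptide+charge) passing the
    hyperscore-ranked target-decoy q-value threshold. Negatives: every
    decoy PSM. Raises :class:`ValidationError` when no positive exists.
    """
    precursors = _precursor_best(psms)
    if not precursors:
        raise ValidationError("no PSMs to assemble a training set from")
    qdf = compute_qvalues(
        [p.hyperscore for p in precursors],
        [p.is_decoy for p in precursors],
        keys=np.arange(len(precursors)),
    )
    passing = set(qdf.loc[(qdf["q"] <= fdr) & (~qdf["is_decoy"]), "key"])
    positives = [precursors[i] for i in sorted(passing)]
    negatives = [p for p in psms if p.is_decoy]
    if not positives:
        raise ValidationError("no target precursors pass the training FDR threshold")
    return positives, negatives


_CHARGE_ONEHOT = 4  # 1+, 2+, 3+, >=4+

PSM_FEATURE_NAMES = (
    "hyperscore", "xcorr", "ln1p_nb", "ln1p_ny", "matched_frac",
    "length", "ln_mass",
    "charge_1", "charge_2", "charge_3", "charge_4plus",
    "delta_mass", "abs_delta_mass", "n_var_mods", "missed_cleavages",
    "rt_error",
)


def psm_feature_matrix(
    psms: Sequence[PSMRecord],
    total_intensity: dict[int, float] | np.ndarray,
    rt_model: RTModel | None = None,
) -> np.ndarray:
    """Feature matrix for the discriminant (one row per PSM).

    ``total_intensity`` maps spectrum id to its total selected intensity
    (denominator of the matched-intensity fraction). The RT error is
    observed minus predicted retention time; it is zero when the RT model
    is absent or disabled.
    """
    n = len(psms)
    X = np.zeros((n, len(PSM_FEATURE_NAMES)))
    if rt_model is not None and rt_model.enabled:
        rt_pred = rt_model.predict([p.peptide for p in psms])
    else:
        rt_pred = None
    for i, p in enumerate(psms):
        ti = (
            total_intensity[p.spectrum_id]
            if not isinstance(total_intensity, dict)
            else total_intensity.get(p.spectrum_id, 0.0)
        )
        matched = p.sum_ib + p.sum_iy
        X[i, 0] = p.hyperscore
        X[i, 1] = p.xcorr
        X[i, 2] = np.log1p(p.n_b)
        X[i, 3] = np.log1p(p.n_y)
        X[i, 4] = matched / ti if ti > 0 else 0.0
        X[i, 5] = p.peptide.length
        X[i, 6] = np.log(p.peptide.neutral_mass)
        z = min(max(p.precursor_charge, 1), _CHARGE_ONEHOT)
        X[i, 6 + z] = 1.0
        X[i, 11] = p.delta_mass
        X[i, 12] = abs(p.delta_mass)
        X[i, 13] = p.peptide.n_var_mods
        X[i, 14] = p.peptide.missed_cleavages
        X[i, 15] = p.retention_time - rt_pred[i] if rt_pred is not None else 0.0
    return X


@dataclass
class DiscriminantModel:
    """Three-layer discriminant over PSM features; higher d = more confident."""

    scaler: StandardScaler
    net: MLPClassifier
    rt_model: RTModel | None
    seed: int
    train_accuracy: float = float("nan")

    def score(
        self,
        psms: Sequence[PSMRecord],
        total_intensity,
    ) -> np.ndarray:
        """Pre-sigmoid discriminant score d for each PSM."""
        X = psm_feature_matrix(psms, total_intensity, self.rt_model)
        Xs = self.scaler.transform(X)
        p = self.net.predict_proba(Xs)[:, 1]
        eps = 1e-12
        p = np.clip(p, eps, 1 - eps)
        return np.log(p / (1 - p))


def train_discriminant(
    positives: Sequence[PSMRecord],
    negatives: Sequence[PSMRecord],
    rt_model: RTModel | None,
    seed: int = 42,
    total_intensity=None,
) -> DiscriminantModel:
    """Train the PSM discriminant from scratch on this run.

    A binary classifier (fully connected 32-16-1, ReLU, Adam, early
    stopping on a 10% split) separates confident targets from decoys.
    Class imbalance is handled by seeded resampling of the minority class
    to the majority size (equivalent in expectation to loss re-weighting).
    PSMs with non-finite features are excluded with a warning.
    """
    if not positives or not negatives:
        raise ValidationError("both positive and negative classes are required")
    if total_intensity is None:
        total_intensity = {}
    Xp = psm_feature_matrix(positives, total_intensity, rt_model)
    Xn = psm_feature_matrix(negatives, total_intensity, rt_model)
    X = np.vstack([Xp, Xn])
    y = np.concatenate([np.ones(len(Xp)), np.zeros(len(Xn))])
    finite = np.isfinite(X).all(axis=1)
    if not finite.all():
        logger.warning("excluded %d PSMs with non-finite features", int((~finite).sum()))
        X, y = X[finite], y[finite]
    if y.min() == y.max():
        raise ValidationError("training classes collapsed after feature filtering")
    rng = np.random.default_rng(seed)
    n_pos = int(y.sum())
    n_neg = int(len(y) - n_pos)
    minority = 1.0 if n_pos < n_neg else 0.0
    idx_min = np.nonzero(y == minority)[0]
    idx_maj = np.nonzero(y != minority)[0]
    extra = rng.choice(idx_min, size=len(idx_maj) - len(idx_min), replace=True)
    idx = np.concatenate([idx_maj, idx_min, extra])
    idx.sort()
    Xb, yb = X[idx], y[idx]
    scaler = StandardScaler().fit(Xb)
    net = MLPClassifier(
        hidden_layer_sizes=(32, 16),
        activation="relu",
        solver="adam",
        random_state=seed,
        max_iter=400,
        early_stopping=True,
        validation_fraction=0.1,
        n_iter_no_change=20,
    )
    net.fit(scaler.transform(Xb), yb)
    acc = float(net.score(scaler.transform(Xb), yb))
    logger.info(
        "discriminant trained on %d positives / %d negatives, accuracy %.3f",
        n_pos, n_neg, acc,
    )
    return DiscriminantModel(
        scaler=scaler, net=net, rt_model=rt_model, seed=seed, train_accuracy=acc
    )


# ---------------------------------------------------------------------------
# Reports


def _protein_records(psms: Sequence[PSMRecord], d: np.ndarray):
    """(accession, best d, is_decoy, supporting peptide keys, shared_only)."""
    acc_score: dict[str, float] = {}
    acc_decoy: dict[str, bool] = {}
    acc_peps: dict[str, set[str]] = {}
    pep_nacc: dict[str, int] = {}
    for p, s in zip(psms, d):
        k = p.peptide.key()
        pep_nacc[k] = max(pep_nacc.get(k, 0), len(p.peptide.protein_accessions))
        for acc in p.peptide.protein_accessions:
            if acc not in acc_score or s > acc_score[acc]:
                acc_score[acc] = float(s)
            acc_decoy[acc] = acc_decoy.get(acc, True) and p.is_decoy
            acc_peps.setdefault(acc, set()).add(k)
    rows = []
    for acc in acc_score:
        peps = sorted(acc_peps[acc])
        shared_only = all(pep_nacc[k] > 1 for k in peps)
        rows.append((acc, acc_score[acc], acc_decoy[acc], peps, shared_only))
    return rows


def final_report(
    psms: Sequence[PSMRecord],
    d: np.ndarray,
    threshold: float = 0.01,
) -> dict[str, pd.DataFrame]:
    """FDR-filtered peptide and protein reports plus the full q tables.

    Peptide level collapses to the best d per modified peptide; protein
    level to the best d per accession (no parsimony: a protein supported
    only by shared peptides is kept and flagged ``shared_only``). Decoys
    are excluded from the reports but retained in the q tables.
    """
    d = np.asarray(d, dtype=np.float64)
    psm_q = compute_qvalues(
        d, [p.is_decoy for p in psms], keys=np.arange(len(psms)), level="psm"
    )
    pep_q = compute_qvalues(
        d, [p.is_decoy for p in psms], keys=[p.peptide.key() for p in psms],
        level="peptide",
    )
    prot_rows = _protein_records(psms, d)
    prot_q = compute_qvalues(
        [r[1] for r in prot_rows],
        [r[2] for r in prot_rows],
        keys=[r[0] for r in prot_rows],
        level="protein",
    )
    # enrich reports
    by_key: dict[str, PSMRecord] = {}
    n_psms: dict[str, int] = {}
    for p in psms:
        k = p.peptide.key()
        n_psms[k] = n_psms.get(k, 0) + 1
        cur = by_key.get(k)
        if cur is None or p.hyperscore > cur.hyperscore:
            by_key[k] = p
    peptides = pep_q[(~pep_q["is_decoy"]) & (pep_q["q"] <= threshold)].copy()
    peptides["sequence"] = [by_key[k].peptide.sequence for k in peptides["key"]]
    peptides["modifications"] = [by_key[k].peptide.mod_string() for k in peptides["key"]]
    peptides["n_psms"] = [n_psms[k] for k in peptides["key"]]
    peptides["proteins"] = [
        ";".join(by_key[k].peptide.protein_accessions) for k in peptides["key"]
    ]
    prot_meta = {r[0]: r for r in prot_rows}
    proteins = prot_q[(~prot_q["is_decoy"]) & (prot_q["q"] <= threshold)].copy()
    proteins["peptides"] = [";".join(prot_meta[a][3]) for a in proteins["key"]]
    proteins["shared_only"] = [prot_meta[a][4] for a in proteins["key"]]
    return {
        "psm_q": psm_q,
        "peptide_q": pep_q,
        "protein_q": prot_q,
        "peptides": peptides.reset_index(drop=True),
        "proteins": proteins.reset_index(drop=True),
    }


@dataclass
class ValidationResult:
    reports: dict[str, pd.DataFrame]
    d: np.ndarray
    rt_model: RTModel | None
    discriminant: DiscriminantModel | None
    fallback: bool
    log: dict


def run_validation(
    psms: Sequence[PSMRecord],
    total_intensity,
    seed: int = 42,
    fdr: float = 0.01,
) -> ValidationResult:
    """Full validation stage: training-set assembly, RT model, discriminant,
    q-values, and reports.

    If no training set can be assembled (e.g. nothing passes the training
    FDR, or there are no decoys), the pipeline falls back to ranking by
    hyperscore with a warning; reports are still produced.
    """
    psms = list(psms)
    log: dict = {"n_psms": len(psms)}
    try:
        positives, negatives = assemble_training_set(psms, fdr=fdr)
        log["n_positives"] = len(positives)
        log["n_negatives"] = len(negatives)
        if not negatives:
            raise ValidationError("no decoy PSMs for the negative class")
        # RT model on unique confident target peptides
        rt_best: dict[str, PSMRecord] = {}
        for p in positives:
            k = p.peptide.key()
            if k not in rt_best or p.hyperscore > rt_best[k].hyperscore:
                rt_best[k] = p
        rt_model = train_rt_model(
            [p.peptide for p in rt_best.values()],
            [p.retention_time for p in rt_best.values()],
            seed=seed,
        )
        log["rt_model"] = rt_model.kind
        log["rt_val_loss"] = rt_model.val_loss
        disc = train_discriminant(
            positives, negatives, rt_model, seed=seed, total_intensity=total_intensity
        )
        log["discriminant_accuracy"] = disc.train_accuracy
        d = disc.score(psms, total_intensity)
        fallback = False
    except ValidationError as err:
        logger.warning("validation fallback to hyperscore ranking: %s", err)
        d = np.array([p.hyperscore for p in psms], dtype=np.float64)
        rt_model, disc, fallback = None, None, True
        log["fallback"] = str(err)
    reports = final_report(psms, d, threshold=fdr)
    log["n_peptides_reported"] = int(len(reports["peptides"]))
    log["n_proteins_reported"] = int(len(reports["proteins"]))
    return ValidationResult(
        reports=reports, d=d, rt_model=rt_model, discriminant=disc,
        fallback=fallback, log=log,
    )
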