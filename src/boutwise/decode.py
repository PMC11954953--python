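"""Shuffle-controlled behavioral decoding from neural embeddings.

The decoder is a bootstrap-aggregated ensemble of decision trees (random
forest) fit on a random 70/30 train/test split of the embedded points.
Two control quantities accompany every decoding accuracy:

* a label-shuffle distribution — the trained decoder re-scored against
  uniformly permuted labels (1000 permutations by default), giving the
  chance level implied by the class structure alone;
* the ensemble's out-of-bag (OOB) error, both for the real labels and
  for decoders trained on shuffled labels.

A real code in the population should produce accuracy well above the
shuffle distribution and an OOB error well below the shuffled-label OOB.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from sklearn.ensemble import RandomForestClassifier

from .errors import ParameterError, ValidationError
from .rng import stage_rng, stage_seed_sequence
from .embedding import Embedding, EmbeddingConfig, apply_encoder, train_embedding
from .types import LongitudinalMap, Session

__all__ = [
    "fit_decoder",
    "shuffle_control",
    "expected_shuffle_accuracy",
    "oob_under_label_shuffle",
    "DecodingReport",
    "decode_embedding",
    "cross_behavior_decode",
    "decode_across_animals",
    "bout_labels",
]

logger = logging.getLogger(__name__)


def bout_labels(session: Session) -> np.ndarray:
    """Per-frame binary bout/no-bout labels for a session."""
    tm = session.traces
    return session.bouts.frame_mask(tm.frame_rate, tm.n_frames).astype(int)


@dataclass
class FittedDecoder:
    model: RandomForestClassifier
    accuracy: float
    oob_error: float
    train_idx: np.ndarray
    test_idx: np.ndarray
    test_predictions: np.ndarray


def _split_indices(
    n: int, labels: np.ndarray, train_frac: float, rng: np.random.Generator,
    max_retries: int = 20,
) -> Tuple[np.ndarray, np.ndarray]:
    """Random-order 70/30 split, resampled until both classes appear on
    both sides (up to a retry cap)."""
    n_train = int(round(train_frac * n))
    if not (0 < n_train < n):
        raise ParameterError("split leaves an empty train or test set")
    for _ in range(max_retries):
        perm = rng.permutation(n)
        train, test = perm[:n_train], perm[n_train:]
        if (
            np.unique(labels[train]).size >= 2
            and np.unique(labels[test]).size >= 2
        ):
            return train, test
    raise ValidationError(
        "could not draw a split with both classes on both sides"
    )


def fit_decoder(
    embedding: Embedding | np.ndarray,
    labels: Optional[np.ndarray] = None,
    train_frac: float = 0.70,
    seed: int = 0,
    n_estimators: int = 100,
) -> FittedDecoder:
    """Random-forest decoder on a random 70/30 split.

    Returns test-set accuracy and the forest's out-of-bag error on the
    training split.
    """
    points = embedding.points if isinstance(embedding, Embedding) else embedding
    if labels is None:
        if not isinstance(embedding, Embedding):
            raise ParameterError("labels required when passing a raw array")
        labels = embedding.labels
    labels = np.asarray(labels)
    if np.unique(labels).size < 2:
        raise ValidationError("need at least 2 classes to decode")

    rng = stage_rng(seed, "decode/split")
    train, test = _split_indices(points.shape[0], labels, train_frac, rng)
    rf_seed = int(stage_seed_sequence(seed, "decode/forest").generate_state(1)[0] % (2**31))
    model = RandomForestClassifier(
        n_estimators=n_estimators,
        oob_score=True,
        random_state=rf_seed,
        n_jobs=1,
    )
    model.fit(points[train], labels[train])
    pred = model.predict(points[test])
    accuracy = float(np.mean(pred == labels[test]))
    oob_error = float(1.0 - model.oob_score_)
    return FittedDecoder(
        model=model,
        accuracy=accuracy,
        oob_error=oob_error,
        train_idx=train,
        test_idx=test,
        test_predictions=pred,
    )


def shuffle_control(
    decoder: FittedDecoder,
    labels: np.ndarray,
    n_perm: int = 1000,
    seed: int = 0,
    permutations: Optional[Sequence[np.ndarray]] = None,
    block_s: Optional[float] = None,
    frame_rate: Optional[float] = None,
) -> np.ndarray:
    """Accuracy of the trained decoder against permuted test labels.

    By default test labels are permuted uniformly; ``block_s`` switches to
    a block permutation (contiguous blocks of that duration are permuted
    as units) for autocorrelation-aware nulls. ``permutations`` lets tests
    inject explicit permutations (e.g. the identity).
    """
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    test_labels = np.asarray(labels)[decoder.test_idx]
    pred = decoder.test_predictions
    n = test_labels.size
    rng = stage_rng(seed, "decode/shuffle")

    accs = np.empty(n_perm if permutations is None else len(permutations))
    if permutations is not None:
        for k, perm in enumerate(permutations):
            accs[k] = np.mean(pred == test_labels[perm])
        return accs

    if block_s is not None:
        if frame_rate is None:
            raise ParameterError("block_s requires frame_rate")
        block = max(1, int(round(block_s * frame_rate)))
        n_blocks = int(np.ceil(n / block))
        for k in range(n_perm):
            order = rng.permutation(n_blocks)
            idx = np.concatenate(
                [np.arange(b * block, min((b + 1) * block, n)) for b in order]
            )
            accs[k] = np.mean(pred == test_labels[idx])
    else:
        for k in range(n_perm):
            accs[k] = np.mean(pred == test_labels[rng.permutation(n)])
    return accs


def expected_shuffle_accuracy(pred: np.ndarray, true: np.ndarray) -> float:
    """Closed-form mean accuracy under uniform label permutation:
    sum_c n_pred(c) * n_true(c) / n^2."""
    pred = np.asarray(pred)
    true = np.asarray(true)
    n = true.size
    classes = np.unique(np.concatenate([pred, true]))
    return float(
        sum((pred == c).sum() * (true == c).sum() for c in classes) / n**2
    )


def oob_under_label_shuffle(
    points: np.ndarray,
    labels: np.ndarray,
    n_shuffles: int = 5,
    seed: int = 0,
    n_estimators: int = 100,
) -> float:
    """Mean OOB error of forests trained on label-shuffled data."""
    rng = stage_rng(seed, "decode/oob-shuffle")
    errs = []
    for k in range(n_shuffles):
        perm = rng.permutation(labels.size)
        rf_seed = int(rng.integers(2**31))
        model = RandomForestClassifier(
            n_estimators=n_estimators, oob_score=True, random_state=rf_seed,
            n_jobs=1,
        )
        model.fit(points, np.asarray(labels)[perm])
        errs.append(1.0 - model.oob_score_)
    return float(np.mean(errs))


@dataclass
class DecodingReport:
    """Actual vs label-shuffled decoding for one embedding/decoder pair."""

    accuracy_actual: float
    accuracy_shuffled_mean: float
    accuracy_shuffled_q025: float
    accuracy_shuffled_q975: float
    oob_actual: float
    oob_shuffled: float
    split_spec: Dict
    n_perm: int
    seed: int
    extra: Dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for a in (self.accuracy_actual, self.accuracy_shuffled_mean):
            if not (0 <= a <= 1):
                raise ValidationError(f"accuracy {a} outside [0, 1]")

    def to_dict(self) -> Dict:
        d = self.__dict__.copy()
        return d


def decode_embedding(
    embedding: Embedding,
    n_perm: int = 1000,
    seed: int = 0,
    train_frac: float = 0.70,
    n_estimators: int = 100,
    n_oob_shuffles: int = 5,
) -> DecodingReport:
    """Full decoding report: RF fit, shuffle control, actual/shuffled OOB."""
    dec = fit_decoder(embedding, train_frac=train_frac, seed=seed,
                      n_estimators=n_estimators)
    accs = shuffle_control(dec, embedding.labels, n_perm=n_perm, seed=seed)
    oob_shuf = oob_under_label_shuffle(
        embedding.points[dec.train_idx],
        embedding.labels[dec.train_idx],
        n_shuffles=n_oob_shuffles,
        seed=seed,
        n_estimators=n_estimators,
    )
    return DecodingReport(
        accuracy_actual=dec.accuracy,
        accuracy_shuffled_mean=float(accs.mean()),
        accuracy_shuffled_q025=float(np.quantile(accs, 0.025)),
        accuracy_shuffled_q975=float(np.quantile(accs, 0.975)),
        oob_actual=dec.oob_error,
        oob_shuffled=oob_shuf,
        split_spec={"train": train_frac, "test": 1 - train_frac},
        n_perm=n_perm,
        seed=seed,
        extra={"encoder": embedding.meta.get("encoder")},
    )


def _shared_cell_traces(
    session: Session, lmap: LongitudinalMap, session_id: str,
    shared_globals: List[str],
):
    local = lmap.globals_in(session_id)
    cell_order = [local[g] for g in shared_globals]
    return session.traces.subset(cell_order)


def cross_behavior_decode(
    session_a: Session,
    session_b: Session,
    lmap: LongitudinalMap,
    config: Optional[EmbeddingConfig] = None,
    n_perm: int = 1000,
    seed: int = 0,
    transfer_decoder: bool = False,
    n_estimators: int = 100,
) -> DecodingReport:
    """Train the encoder on behavior A, decode behavior B on shared cells.

    The encoder is fit on A's shared-cell traces, applied frozen to B's
    traces, and a fresh decoder is trained/tested on the B-embedded
    points against B's bout labels (the re-train-decoder reading);
    ``transfer_decoder=True`` instead carries A's decoder over and scores
    it on all B points. Shuffle control uses B's labels either way.
    """
    id_a = f"{session_a.animal_id}/{session_a.stimulus}"
    id_b = f"{session_b.animal_id}/{session_b.stimulus}"
    shared = lmap.shared_globals(id_a, id_b)
    if not shared:
        raise ValidationError(f"no shared cells between {id_a} and {id_b}")
    traces_a = _shared_cell_traces(session_a, lmap, id_a, shared)
    traces_b = _shared_cell_traces(session_b, lmap, id_b, shared)

    cfg = config or EmbeddingConfig()
    emb_a = train_embedding(traces_a, bout_labels(session_a), cfg)
    emb_b = apply_encoder(emb_a, traces_b, bout_labels(session_b))

    if transfer_decoder:
        dec_a = fit_decoder(emb_a, seed=seed, n_estimators=n_estimators)
        pred_b = dec_a.model.predict(emb_b.points)
        accuracy = float(np.mean(pred_b == emb_b.labels))
        dec_for_shuffle = FittedDecoder(
            model=dec_a.model,
            accuracy=accuracy,
            oob_error=dec_a.oob_error,
            train_idx=np.arange(0),
            test_idx=np.arange(emb_b.points.shape[0]),
            test_predictions=pred_b,
        )
        accs = shuffle_control(dec_for_shuffle, emb_b.labels, n_perm=n_perm, seed=seed)
        oob_shuf = oob_under_label_shuffle(
            emb_a.points, emb_a.labels, seed=seed, n_estimators=n_estimators
        )
        oob_actual = dec_a.oob_error
    else:
        report = decode_embedding(
            emb_b, n_perm=n_perm, seed=seed, n_estimators=n_estimators
        )
        report.extra.update(
            {"mode": "cross-behavior", "train_session": id_a,
             "eval_session": id_b, "n_shared_cells": len(shared)}
        )
        return report

    return DecodingReport(
        accuracy_actual=accuracy,
        accuracy_shuffled_mean=float(accs.mean()),
        accuracy_shuffled_q025=float(np.quantile(accs, 0.025)),
        accuracy_shuffled_q975=float(np.quantile(accs, 0.975)),
        oob_actual=oob_actual,
        oob_shuffled=oob_shuf,
        split_spec={"train": "session A", "test": "session B (all points)"},
        n_perm=n_perm,
        seed=seed,
        extra={"mode": "cross-behavior-transfer-decoder",
               "train_session": id_a, "eval_session": id_b,
               "n_shared_cells": len(shared)},
    )


def decode_across_animals(
    embeddings: Sequence[Embedding],
    animal_ids: Sequence[str],
    n_perm: int = 1000,
    seed: int = 0,
    train_frac: float = 0.70,
    n_estimators: int = 100,
) -> DecodingReport:
    """Pooled decoding with an animal-stratified split.

    Each animal's embedded points are split 70/30 independently, then
    pooled, so every animal contributes to both sides of the split.
    """
    if len(embeddings) != len(animal_ids):
        raise ParameterError("one animal id per embedding required")
    dims = {e.points.shape[1] for e in embeddings}
    if len(dims) != 1:
        raise ParameterError("embeddings must share latent dimension")

    rng = stage_rng(seed, "decode/across-animals")
    train_X, train_y, test_X, test_y = [], [], [], []
    for emb in embeddings:
        tr, te = _split_indices(emb.points.shape[0], emb.labels, train_frac, rng)
        train_X.append(emb.points[tr])
        train_y.append(emb.labels[tr])
        test_X.append(emb.points[te])
        test_y.append(emb.labels[te])
    Xtr = np.vstack(train_X)
    ytr = np.concatenate(train_y)
    Xte = np.vstack(test_X)
    yte = np.concatenate(test_y)

    rf_seed = int(stage_seed_sequence(seed, "decode/forest").generate_state(1)[0] % (2**31))
    model = RandomForestClassifier(
        n_estimators=n_estimators, oob_score=True, random_state=rf_seed, n_jobs=1
    )
    model.fit(Xtr, ytr)
    pred = model.predict(Xte)
    dec = FittedDecoder(
        model=model,
        accuracy=float(np.mean(pred == yte)),
        oob_error=float(1.0 - model.oob_score_),
        train_idx=np.arange(Xtr.shape[0]),
        test_idx=np.arange(Xte.shape[0]),
        test_predictions=pred,
    )
    accs = shuffle_control(dec, yte, n_perm=n_perm, seed=seed)
    oob_shuf = oob_under_label_shuffle(Xtr, ytr, seed=seed, n_estimators=n_estimators)
    return DecodingReport(
        accuracy_actual=dec.accuracy,
        accuracy_shuffled_mean=float(accs.mean()),
        accuracy_shuffled_q025=float(np.quantile(accs, 0.025)),
        accuracy_shuffled_q975=float(np.quantile(accs, 0.975)),
        oob_actual=dec.oob_error,
        oob_shuffled=oob_shuf,
        split_spec={"train": train_frac, "test": 1 - train_frac,
                    "stratified_by": "animal"},
        n_perm=n_perm,
        seed=seed,
        extra={"mode": "across-animals", "animals": list(animal_ids)},
    )
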