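"""End-to-end experiment orchestration on synthetic corpora.

Ties the generator, the feature pipeline, ground-truth labeling, the
train/validation/test split, and SCG training into one call, so the same
routine backs the CLI, the test suite, and result reproduction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .classifier import ConfusionReport, TrainedNetwork, evaluate, init_network, scg_train
from .features import run_pipeline
from .labeling import LabeledDataset, dataset_from_runs, split_dataset
from .synthetic import SynthSpec, generate_corpus

__all__ = ["CorpusExperiment", "corpus_experiment"]


@dataclass
class CorpusExperiment:
    """Everything a corpus-level training run produced."""

    dataset: LabeledDataset
    train: LabeledDataset
    val: LabeledDataset
    test: LabeledDataset
    net: TrainedNetwork
    reports: dict[str, ConfusionReport]
    ground_truths: list
    results: list

    @property
    def test_accuracy(self) -> float:
        return self.reports["test"].accuracy


def _sub_seeds(seed: int, names: tuple[str, ...]) -> dict[str, int]:
    ss = np.random.SeedSequence(seed).spawn(len(names))
    return {
        n: int(s.generate_state(1, dtype=np.uint32)[0] % (2**31))
        for n, s in zip(names, ss)
    }


def corpus_experiment(
    n_images: int,
    seed: int,
    spec: SynthSpec | None = None,
    max_iter: int = 400,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    n_hidden: int = 20,
) -> CorpusExperiment:
    """Generate a corpus, extract and label candidates, train, and evaluate.

    One global seed fans out to the generator, perimeter-cut, split, and
    weight-init sub-seeds, so the whole experiment is reproducible from a
    single integer.
    """
    seeds = _sub_seeds(seed, ("synth", "cut", "split", "init"))
    if spec is None:
        spec = SynthSpec()
    corpus = generate_corpus(n_images, seed=seeds["synth"], spec=spec)
    runs = []
    for img, gt, labels in corpus:
        result = run_pipeline(img, rng_seed=seeds["cut"])
        runs.append((result, labels))
    ds = dataset_from_runs(runs, spec.scale)
    if ds.n_spine == 0 or ds.n_non_spine == 0:
        raise RuntimeError("corpus produced a single-class dataset")
    tr, va, te = split_dataset(ds, fractions, seed=seeds["split"])
    net = init_network(seeds["init"], n_hidden=n_hidden)
    scg_train(net, (tr.X, tr.y), (va.X, va.y), max_iter=max_iter)
    reports = {
        "train": evaluate(net, tr.X, tr.y),
        "val": evaluate(net, va.X, va.y),
        "test": evaluate(net, te.X, te.y),
    }
    return CorpusExperiment(
        dataset=ds,
        train=tr,
        val=va,
        test=te,
        net=net,
        reports=reports,
        ground_truths=[gt for _, gt, _ in corpus],
        results=[r for r, _ in runs],
    )
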