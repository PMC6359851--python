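"""End-to-end convenience pipeline over the individual modules.

Chains the literal production path on a simulated experiment: windows ->
peak-intersection labels -> feature matrix -> balanced dataset -> fitted
model.  Used by the examples and by validation studies; each step is the
same public function a user would call on real FASTA/BED inputs.
"""

from __future__ import annotations

import numpy as np

from . import dataset as ds
from . import features as ft
from . import io_formats as io
from . import model as md
from .synthetic import CooperationSpec, SimulatedExperiment, simulate_experiment


def run_simulated_study(spec: CooperationSpec, seed: int = 0,
                        scorer: str = "best_hit", nfolds: int = 10,
                        mode: str = "uncontrolled", n_lambda: int = 60):
    """Simulate one experiment and fit a model on it.

    Returns ``(sim, labeled_dataset, model)``.  Labels are derived by
    intersecting the emitted windows with the emitted peak intervals (the
    same path real ChIP-seq data takes), the dataset is balanced with the
    requested sampling mode, and the model is fitted with ``nfolds``-fold
    cross-validation.
    """
    rng = np.random.default_rng(seed)
    sim = simulate_experiment(spec, seed=int(rng.integers(0, 2**31 - 1)))
    labels = io.intersect_labels(sim.windows, sim.peaks)
    X = ft.build_feature_matrix(sim.windows, spec.motifs, scorer=scorer)
    data = ds.make_dataset(
        X, labels, mode=mode,
        seed=int(rng.integers(0, 2**31 - 1)),
        expression=sim.expression if mode == "expression_controlled" else None,
        provenance=f"simulated target={spec.target_motif}",
    )
    fitted = md.fit(data, nfolds=nfolds,
                    seed=int(rng.integers(0, 2**31 - 1)), n_lambda=n_lambda)
    return sim, data, fitted
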