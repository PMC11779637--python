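"""Deterministic seed management.

One user-facing integer seed is expanded into independent per-generator
streams via :class:`numpy.random.SeedSequence` with a fixed integer tag per
generator name.  Adding a new generator (new tag) never perturbs the streams
of existing ones, and a fixed seed yields bitwise-identical output across
runs and platforms.
"""

from __future__ import annotations

import numpy as np

# Stable tags; append-only. Never renumber.
_GENERATOR_TAGS = {
    "tumor_genomes": 1,
    "progression_cohort": 2,
    "expression_cohort": 3,
    "survival_cohort": 4,
    "cell_table": 5,
    "gsea_permutation": 6,
    "mi_null": 7,
    "module_search": 8,
    "pc1_permutation": 9,
    "clustering": 10,
}


def child_rng(seed: int, name: str) -> np.random.Generator:
    """Return the dedicated RNG stream for ``name`` under the global ``seed``."""
    try:
        tag = _GENERATOR_TAGS[name]
    except KeyError:
        raise KeyError(f"unknown generator name {name!r}; register a tag in _GENERATOR_TAGS")
    return np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(tag,)))
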