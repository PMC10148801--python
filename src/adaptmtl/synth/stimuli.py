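"""Stimulus sets: images grouped into semantic categories and two meta-categories.

The task uses 100 images from 10 semantic categories (10 exemplars each);
5 categories depict manmade objects and 5 depict natural objects, so every
image affords a manmade/natural decision.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

MANMADE = "manmade"
NATURAL = "natural"


class ConfigurationError(ValueError):
    """Raised when generator parameters are structurally invalid."""


@dataclass(frozen=True)
class StimulusSet:
    """Stimuli with their semantic category and manmade/natural meta-category.

    Attributes
    ----------
    category_of:
        ``category_of[s]`` is the category id of stimulus ``s``;
        stimulus ids are ``0 .. n_stimuli - 1``.
    meta_of:
        ``meta_of[c]`` is ``"manmade"`` or ``"natural"`` for category ``c``.
    """

    category_of: np.ndarray
    meta_of: tuple[str, ...]

    @property
    def n_stimuli(self) -> int:
        return len(self.category_of)

    @property
    def n_categories(self) -> int:
        return len(self.meta_of)

    @property
    def stimuli(self) -> np.ndarray:
        return np.arange(self.n_stimuli)

    def exemplars(self, category: int) -> np.ndarray:
        return np.flatnonzero(self.category_of == category)

    def meta_of_stimulus(self, stimulus: int) -> str:
        return self.meta_of[int(self.category_of[stimulus])]

    def validate(self) -> None:
        counts = np.bincount(self.category_of, minlength=self.n_categories)
        if not np.all(counts == counts[0]):
            raise ConfigurationError("categories must have equal exemplar counts")
        n_man = sum(m == MANMADE for m in self.meta_of)
        n_nat = sum(m == NATURAL for m in self.meta_of)
        if n_man != n_nat:
            raise ConfigurationError(
                f"meta-categories unbalanced: {n_man} manmade vs {n_nat} natural"
            )


def generate_stimulus_set(
    n_categories: int = 10, n_exemplars: int = 10, seed: int | None = None
) -> StimulusSet:
    """Build a balanced stimulus set.

    Stimulus ``s`` belongs to category ``s // n_exemplars``; the assignment
    of categories to the manmade/natural meta-categories is a seeded random
    half/half split.
    """
    if n_categories < 2 or n_categories % 2 != 0:
        raise ConfigurationError("n_categories must be even and >= 2")
    if n_exemplars < 1:
        raise ConfigurationError("n_exemplars must be >= 1")
    rng = np.random.default_rng(seed)
    category_of = np.repeat(np.arange(n_categories), n_exemplars)
    order = rng.permutation(n_categories)
    meta = [""] * n_categories
    for i, c in enumerate(order):
        meta[c] = MANMADE if i < n_categories // 2 else NATURAL
    sset = StimulusSet(category_of=category_of, meta_of=tuple(meta))
    sset.validate()
    return sset
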