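"""Bookkeeping of the acquisition design.

The study design this package emulates samples three muscles from each
animal, images both cut faces of every muscle sample, and records one
19-band cube per face.
"""

from __future__ import annotations


def acquisition_counts(n_animals: int = 40, n_muscles: int = 3,
                       sides_per_sample: int = 2, n_bands: int = 19
                       ) -> dict[str, int]:
    """Sample, cube and single-band image counts implied by the design."""
    n_samples = n_animals * n_muscles
    n_cubes = n_samples * sides_per_sample
    return {
        "n_samples": n_samples,
        "n_cubes": n_cubes,
        "n_images": n_cubes * n_bands,
    }
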