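"""Cohort generation: many organoids with ground truth and a manifest."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ..archetypes import (
    DEFAULT_ARCHETYPES, LINE_OF, PhenotypeArchetype, jitter_archetype,
)
from .render import DEFAULT_PIXEL_SIZE_UM, GroundTruth, generate_organoid_image


@dataclass
class Cohort:
    """A rendered organoid cohort with per-organoid ground truth."""

    images: list  # list of 2D float arrays
    truths: list  # list of GroundTruth
    manifest: pd.DataFrame

    def __len__(self) -> int:
        return len(self.images)

    @property
    def labels(self) -> np.ndarray:
        return self.manifest["phenotype"].to_numpy()

    @property
    def lines(self) -> np.ndarray:
        return self.manifest["line"].to_numpy()


def generate_cohort(
    spec: dict[str | PhenotypeArchetype, int],
    jitter: float = 0.0,
    seed: int = 0,
    canvas_px: tuple[int, int] = (800, 800),
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM,
    noise_level: float = 0.0,
    out_dir: str | Path | None = None,
) -> Cohort:
    """Render a cohort of organoids.

    ``spec`` maps a phenotype name (or archetype) to the number of
    organoids of that family.  Per-organoid parameters are drawn around
    the archetype defaults with relative jitter; the dataset order is
    shuffled deterministically.  If ``out_dir`` is given, 8-bit PNGs and a
    ``manifest.csv`` with labels and all ground-truth fields are written.
    """
    if not spec:
        raise ValueError("empty cohort spec")
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    entries = []
    for key, count in spec.items():
        if count < 1:
            raise ValueError(f"count for {key!r} must be >= 1")
        arch = DEFAULT_ARCHETYPES[key] if isinstance(key, str) else key
        entries += [arch] * int(count)

    master = np.random.default_rng(seed)
    seeds = master.integers(0, 2**31 - 1, size=len(entries))
    order = master.permutation(len(entries))

    images, truths, rows = [], [], []
    for idx in order:
        arch, sub_seed = entries[idx], int(seeds[idx])
        rng = np.random.default_rng(sub_seed)
        variant = jitter_archetype(arch, jitter, rng)
        img, gt = generate_organoid_image(
            variant, canvas_px=canvas_px, pixel_size_um=pixel_size_um,
            noise_level=noise_level, seed=sub_seed,
        )
        images.append(img)
        truths.append(gt)
        rows.append({
            "file": "", "phenotype": gt.phenotype,
            "line": LINE_OF.get(gt.phenotype, "unknown"),
            **gt.as_dict(),
        })
    manifest = pd.DataFrame(rows)

    if out_dir is not None:
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for i, img in enumerate(images):
            fname = f"organoid_{i:04d}_{truths[i].phenotype}.png"
            iio.imwrite(out / fname, (img * 255).astype(np.uint8))
            manifest.loc[i, "file"] = fname
        manifest.to_csv(out / "manifest.csv", index=False)
    return Cohort(images, truths, manifest)
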