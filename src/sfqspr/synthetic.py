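"""Planted-signal synthetic descriptor matrices and the bundled SF table.

Real descriptor matrices in this domain are small-n (tens of molecules),
wide (hundreds to ~1500 columns), and messy: many columns are constant across
the data set, some are exact duplicates of others, and only a handful
linearly drive the property of interest.  :func:`make_planted` reproduces
exactly that structure with recorded ground truth, so every selector and
model in the package can be tested for recovery without any external
descriptor software.

:func:`table1_fixture` returns the 26 published plasticizer substitution
factors (dimensionless, di(2-ethylhexyl) phthalate = DOP = 1 by definition)
used as the package's bundled real-data target table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .data_io import DescriptorTable


@dataclass
class SyntheticSpec:
    """Recipe for a planted-signal descriptor matrix.

    Defaults emulate a realistic selection problem: 30 molecules, 200
    descriptors of which 5 drive the target linearly with unit effect sizes,
    Gaussian noise with sigma = 0.5, plus 5 constant and 5 duplicated
    nuisance columns.
    """

    n_samples: int = 30
    n_descriptors: int = 200
    n_informative: int = 5
    effects: np.ndarray | None = None
    noise_sigma: float = 0.5
    n_constant: int = 5
    n_duplicates: int = 5
    duplicate_jitter: float = 0.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValueError("need at least one informative descriptor")
        if self.n_informative + self.n_constant + self.n_duplicates > self.n_descriptors:
            raise ValueError("informative + constant + duplicate counts exceed n_descriptors")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.effects is None:
            self.effects = np.ones(self.n_informative)
        else:
            self.effects = np.asarray(self.effects, dtype=float)
            if self.effects.shape != (self.n_informative,):
                raise ValueError("effects must have length n_informative")


@dataclass
class GroundTruth:
    """What the generator planted, for recovery checks."""

    informative_names: list[str]
    constant_names: list[str]
    duplicate_names: dict[str, str]  # duplicate -> informative source
    effects: np.ndarray
    noise_sigma: float
    nuisance_names: list[str] = field(default_factory=list)


def make_planted(spec: SyntheticSpec) -> tuple[DescriptorTable, GroundTruth]:
    """Generate a descriptor table with planted linear signal.

    Informative columns are standard normal; the target is their linear
    combination with the spec's effect sizes plus N(0, sigma^2) noise.
    Nuisance columns are independent standard normal, ``n_constant`` columns
    are constant, and ``n_duplicates`` columns are copies of randomly chosen
    informative columns (exact copies by default, to stress redundancy
    filters).  Column positions are shuffled so the planted columns are not
    identifiable by position; names are uniform (``D0001``...) so they are not
    identifiable by name either.  Fully deterministic given the seed.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, d, k = spec.n_samples, spec.n_descriptors, spec.n_informative
    n_noise = d - k - spec.n_constant - spec.n_duplicates

    X_inf = rng.standard_normal((n, k))
    y = X_inf @ spec.effects + rng.normal(0.0, spec.noise_sigma, size=n)

    X_noise = rng.standard_normal((n, n_noise))
    const_vals = rng.normal(size=spec.n_constant)
    X_const = np.tile(const_vals, (n, 1))
    dup_src = rng.integers(0, k, size=spec.n_duplicates)
    X_dup = X_inf[:, dup_src].copy()
    if spec.duplicate_jitter > 0:
        X_dup += rng.normal(0.0, spec.duplicate_jitter, size=X_dup.shape)

    blocks = np.hstack([X_inf, X_noise, X_const, X_dup])
    roles = (
        [("informative", i) for i in range(k)]
        + [("noise", i) for i in range(n_noise)]
        + [("constant", i) for i in range(spec.n_constant)]
        + [("duplicate", i) for i in range(spec.n_duplicates)]
    )
    perm = rng.permutation(d)
    blocks = blocks[:, perm]
    roles = [roles[j] for j in perm]

    width = max(4, len(str(d)))
    names = [f"D{j + 1:0{width}d}" for j in range(d)]
    informative_names = [""] * k
    constant_names, nuisance_names = [], []
    duplicate_slots: list[tuple[str, int]] = []
    for name, (role, idx) in zip(names, roles):
        if role == "informative":
            informative_names[idx] = name
        elif role == "constant":
            constant_names.append(name)
        elif role == "duplicate":
            duplicate_slots.append((name, idx))
        else:
            nuisance_names.append(name)
    duplicate_names = {
        name: informative_names[dup_src[idx]] for name, idx in duplicate_slots
    }

    table = DescriptorTable(
        molecule_ids=[f"M{i + 1:03d}" for i in range(n)],
        descriptor_names=names,
        values=blocks,
        target=y,
    )
    truth = GroundTruth(
        informative_names=informative_names,
        constant_names=constant_names,
        duplicate_names=duplicate_names,
        effects=spec.effects.copy(),
        noise_sigma=spec.noise_sigma,
        nuisance_names=nuisance_names,
    )
    return table, truth


# 26 plasticizers with published substitution factors (DOP = 1 by definition).
TABLE1_SF: tuple[tuple[str, float], ...] = (
    ("BBP", 0.94),
    ("BOP", 0.94),
    ("DHP", 0.96),
    ("DIHP", 0.97),
    ("DOP", 1.0),
    ("DIOP", 1.01),
    ("DINP", 1.06),
    ("DIDP", 1.1),
    ("DIUP", 1.16),
    ("DTDP", 1.27),
    ("DBP", 0.86),
    ("79P", 1.0),
    ("L9P", 0.99),
    ("7911P", 1.0),
    ("DUP", 1.14),
    ("NODTM", 1.12),
    ("TOTM", 1.17),
    ("TIOTM", 1.19),
    ("TINTM", 1.27),
    ("DOA", 0.93),
    ("DIOA", 0.94),
    ("DINA", 0.98),
    ("DDP", 0.96),
    ("TOF", 1.0),
    ("TCP", 1.31),
    ("DOTP", 1.03),
)


def table1_fixture() -> pd.DataFrame:
    """The bundled 26-plasticizer substitution-factor table.

    Returns a two-column frame (``molecule_id``, ``sf``) at the published
    precision, suitable as the target file of :func:`sfqspr.data_io.load_table`.
    """
    return pd.DataFrame(TABLE1_SF, columns=["molecule_id", "sf"])


def synthetic_descriptors_for(
    molecule_ids: list[str], n_descriptors: int = 120, rng_seed: int = 0
) -> DescriptorTable:
    """Synthetic stand-in descriptor matrix for a given molecule list.

    Real descriptor software is an external preprocessing step; this helper
    produces a plausibly shaped random matrix (synthetic, no chemical
    meaning) so that plumbing around the bundled SF table can be exercised.
    """
    rng = np.random.default_rng(rng_seed)
    width = max(4, len(str(n_descriptors)))
    return DescriptorTable(
        molecule_ids=list(molecule_ids),
        descriptor_names=[f"D{j + 1:0{width}d}" for j in range(n_descriptors)],
        values=rng.standard_normal((len(molecule_ids), n_descriptors)),
        target=None,
    )
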