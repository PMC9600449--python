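import numpy as np
import pandas as pd
import pytest

from lymphpanel.models import FilterConfig, VariantRecord
from lymphpanel.simulate import SimulationConfig, build_default_panel


@pytest.fixture(scope="session")
def panel():
    return build_default_panel()


@pytest.fixture
def config():
    return FilterConfig()


@pytest.fixture
def sim_config():
    return SimulationConfig(seed=123)


def make_variant(**kwargs) -> VariantRecord:
    """Variant factory with neutral defaults; override per test."""
    defaults = dict(
        sample_id="S1",
        gene="PIM1",
        chrom="chr6",
        pos=37138000,
        ref="A",
        alt="G",
        vaf=0.35,
        depth=900,
        variant_class=5,
        protein_change="",
        cadd_phred=None,
        n_damaging_predictions=None,
        mutation_type="nonsynonymous",
    )
    defaults.update(kwargs)
    return VariantRecord(**defaults)


def random_variant(rng: np.random.Generator) -> VariantRecord:
    """Randomized record stressing every branch of the retention cascade:
    hotspots, boundary VAFs, all classes, missing annotations."""
    roll = rng.random()
    if roll < 0.08:
        return make_variant(
            gene="MYD88", chrom="chr3", pos=38182641, ref="T", alt="C",
            protein_change="L265P", variant_class=int(rng.integers(3, 6)),
            vaf=float(rng.choice([0.0, 0.017, 0.08, rng.uniform(0, 1)])),
        )
    if roll < 0.16:
        return make_variant(
            gene="CD79B", chrom="chr17", pos=62006799, ref="T", alt="C",
            protein_change=str(rng.choice(["Y196S", "Y196H", "Y196N", "Y196F"])),
            variant_class=int(rng.integers(3, 6)),
            vaf=float(rng.choice([0.0, 0.075, rng.uniform(0, 1)])),
        )
    cadd = None if rng.random() < 0.3 else float(rng.uniform(0, 45))
    ndam = None if rng.random() < 0.3 else int(rng.integers(0, 5))
    # cluster VAFs around the 10% decision boundary
    vaf = float(rng.choice([rng.uniform(0, 1), rng.uniform(0.08, 0.12), 0.1, 0.0999]))
    return make_variant(
        gene=str(rng.choice(["PIM1", "MYC", "KMT2D", "MYD88", "CD79B", "TP53"])),
        pos=int(rng.integers(1, 10**6)),
        protein_change=str(rng.choice(["", "A10V", "L265P", "Y196S"])),
        variant_class=int(rng.integers(1, 6)),
        vaf=vaf,
        cadd_phred=cadd,
        n_damaging_predictions=ndam,
    )
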