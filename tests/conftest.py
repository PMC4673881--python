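import numpy as np
import pytest

from samgwas.config import SimConfig
from samgwas.morphometrics import SAMContour


def exact_parabola_contour(h=100.0, r=80.0, n=51, genotype="g", replicate="r1"):
    """Noise-free points on y = h − (h/r²)x², the generator's model."""
    x = np.linspace(-r, r, n)
    return SAMContour(genotype=genotype, replicate=replicate, x=x, y=h - (h / r**2) * x**2)


@pytest.fixture
def parabola_contour():
    return exact_parabola_contour()


@pytest.fixture
def tiny_cfg():
    return SimConfig(seed=7, n_genotypes=25, n_replicates=4, n_snps=400, noise_sd=1.0)
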