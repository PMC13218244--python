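import numpy as np
import pytest


def sierpinski_carpet(iterations: int, cell_px: int = 1) -> np.ndarray:
    """Sierpinski carpet rasterized at ``cell_px`` pixels per finest cell."""
    m = np.ones((1, 1), bool)
    for _ in range(iterations):
        z = np.zeros_like(m)
        m = np.block([[m, m, m], [m, z, m], [m, m, m]])
    if cell_px > 1:
        m = np.kron(m, np.ones((cell_px, cell_px), bool))
    return m


def sierpinski_triangle(iterations: int, cell_px: int = 1) -> np.ndarray:
    """Sierpinski triangle on a 2**iterations grid (Pascal parity)."""
    n = 2 ** iterations
    y, x = np.mgrid[0:n, 0:n]
    m = (x & y) == 0
    if cell_px > 1:
        m = np.kron(m, np.ones((cell_px, cell_px), bool))
    return m


@pytest.fixture(scope="session")
def straight_line_512():
    img = np.zeros((512, 512), bool)
    img[256, 10:500] = True
    return img


@pytest.fixture(scope="session")
def filled_rect_512():
    img = np.zeros((512, 512), bool)
    img[100:400, 80:430] = True
    return img


@pytest.fixture(scope="session")
def filled_disc_512():
    yy, xx = np.mgrid[0:512, 0:512]
    return (xx - 256) ** 2 + (yy - 256) ** 2 <= 240 ** 2


@pytest.fixture(scope="session")
def carpet4():
    """4-iteration carpet at 3 px per cell (243 x 243)."""
    return sierpinski_carpet(4, cell_px=3)


@pytest.fixture(scope="session")
def triangle5():
    """5-iteration triangle at 8 px per cell (256 x 256)."""
    return sierpinski_triangle(5, cell_px=8)
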