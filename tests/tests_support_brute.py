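"""Shared independent oracles for the test suite: brute-force nearest-boundary
search and random connected-mask generation."""

import numpy as np


def brute_force_signed_distances(mask, cell_mask, membrane, pixel_size):
    """All-pairs nearest-membrane search, signed by interiority."""
    boundary = np.argwhere(membrane)
    out = []
    for r, c in np.argwhere(mask):
        d2 = ((boundary[:, 0] - r) ** 2 + (boundary[:, 1] - c) ** 2).min()
        sign = 1.0 if cell_mask[r, c] else -1.0
        out.append(sign * np.sqrt(float(d2)) * pixel_size)
    return np.array(out)


def random_connected_mask(rng, size):
    """One connected blob from thresholded smoothed noise."""
    from scipy.ndimage import binary_fill_holes, gaussian_filter, label

    field = gaussian_filter(rng.normal(size=(size, size)), sigma=size / 8)
    mask = field > np.quantile(field, 0.7)
    labels, n = label(mask, structure=np.ones((3, 3)))
    if n == 0:
        mask = np.zeros((size, size), dtype=bool)
        mask[size // 2 - 2 : size // 2 + 2, size // 2 - 2 : size // 2 + 2] = True
        return mask
    sizes = np.bincount(labels.ravel())[1:]
    return binary_fill_holes(labels == (int(np.argmax(sizes)) + 1))
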