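"""Independent brute-force reference implementations used only by tests.

These deliberately avoid the library paths they check (no scikit-image, no
vectorized tricks): plain breadth-first search over pixel neighbours.
"""

from collections import deque

NEIGHBOURS_8 = [
    (-1, -1), (-1, 0), (-1, 1),
    (0, -1), (0, 1),
    (1, -1), (1, 0), (1, 1),
]


def flood_fill_area(pixels, seed, threshold):
    """Pixel set of the 8-connected component >= threshold containing seed.

    Returns a frozenset of (row, col); empty when the seed itself is below
    the threshold.
    """
    rows = len(pixels)
    cols = len(pixels[0])
    r0, c0 = seed
    if pixels[r0][c0] < threshold:
        return frozenset()
    seen = {(r0, c0)}
    queue = deque([(r0, c0)])
    while queue:
        r, c = queue.popleft()
        for dr, dc in NEIGHBOURS_8:
            rr, cc = r + dr, c + dc
            if 0 <= rr < rows and 0 <= cc < cols and (rr, cc) not in seen:
                if pixels[rr][cc] >= threshold:
                    seen.add((rr, cc))
                    queue.append((rr, cc))
    return frozenset(seen)


def connected_components(pixels, threshold):
    """All 8-connected components >= threshold, as a list of frozensets."""
    rows = len(pixels)
    cols = len(pixels[0])
    assigned = set()
    components = []
    for r in range(rows):
        for c in range(cols):
            if pixels[r][c] >= threshold and (r, c) not in assigned:
                comp = flood_fill_area(pixels, (r, c), threshold)
                assigned |= comp
                components.append(comp)
    return components
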