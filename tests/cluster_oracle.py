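"""Brute-force flood-fill oracle for cluster formation.

Deliberately naive (explicit loops, BFS over sample tuples) and fully
independent of the package's labeling implementation: used to cross-check
`pceeg.stats.form_clusters` including the spatial-neighbor pre-filter.
"""

from collections import deque

import numpy as np


def oracle_clusters(F, slope, threshold, neighbor_map, channel_names):
    """All sign-pure clusters as (frozenset of (c, f, t), value, sign) tuples."""
    n_ch, n_f, n_t = F.shape
    idx_of = {ch: i for i, ch in enumerate(channel_names)}
    nb_idx = {
        idx_of[ch]: sorted(idx_of[nb] for nb in nbs)
        for ch, nbs in neighbor_map.items()
    }
    out = []
    for sign, keep in (("positive", slope > 0), ("negative", slope < 0)):
        supra = (F > threshold) & keep
        # spatial pre-filter: need one supra neighbor channel at same (f, t)
        filtered = np.zeros_like(supra)
        for c in range(n_ch):
            for f in range(n_f):
                for t in range(n_t):
                    if supra[c, f, t] and any(
                        supra[c2, f, t] for c2 in nb_idx[c]
                    ):
                        filtered[c, f, t] = True
        seen = np.zeros_like(filtered)
        for c in range(n_ch):
            for f in range(n_f):
                for t in range(n_t):
                    if not filtered[c, f, t] or seen[c, f, t]:
                        continue
                    members = []
                    queue = deque([(c, f, t)])
                    seen[c, f, t] = True
                    while queue:
                        cc, ff, tt = queue.popleft()
                        members.append((cc, ff, tt))
                        candidates = (
                            [(cc, ff - 1, tt), (cc, ff + 1, tt),
                             (cc, ff, tt - 1), (cc, ff, tt + 1)]
                            + [(c2, ff, tt) for c2 in nb_idx[cc]]
                        )
                        for c2, f2, t2 in candidates:
                            if (
                                0 <= f2 < n_f and 0 <= t2 < n_t
                                and filtered[c2, f2, t2] and not seen[c2, f2, t2]
                            ):
                                seen[c2, f2, t2] = True
                                queue.append((c2, f2, t2))
                    value = sum(F[m] for m in members)
                    out.append((frozenset(members), value, sign))
    return out


def random_stat_instance(rng, montage, n_f, n_t, supra_frac=0.25):
    """A random F/slope map with roughly the requested supra-threshold density."""
    shape = (montage.n_channels, n_f, n_t)
    F = rng.exponential(1.0, size=shape)
    slope = rng.standard_normal(shape)
    threshold = float(np.quantile(F, 1.0 - supra_frac))
    return F, slope, threshold
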