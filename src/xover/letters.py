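"""Compact letter display for pairwise comparison matrices."""

from __future__ import annotations


def compact_letters(order, differs) -> dict:
    """Assign letters so two groups share one iff not significantly
    different.

    ``order`` lists group names sorted by the statistic (highest first,
    which receives 'a'); ``differs`` is a callable differs(x, y) -> bool,
    symmetric, giving significance of the pairwise comparison. Greedy
    insert-and-absorb: each group joins every existing letter it is
    compatible with; if none, it opens a new letter and pulls in earlier
    compatible groups.
    """
    order = list(order)
    groups: list[set] = []
    seen: list = []
    for name in order:
        placed = False
        for g in groups:
            if all(not differs(name, other) for other in g):
                g.add(name)
                placed = True
        if not placed:
            fresh = {name}
            for other in seen:
                if not differs(name, other) and \
                        all(not differs(other, m) for m in fresh):
                    fresh.add(other)
            groups.append(fresh)
        seen.append(name)
    # drop letter sets fully contained in another (redundant labels)
    kept = [g for g in groups
            if not any(g < h for h in groups)]
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    letters = {name: "" for name in order}
    for letter, g in zip(alphabet, kept):
        for name in order:
            if name in g:
                letters[name] += letter
    return letters
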