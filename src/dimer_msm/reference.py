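"""Literature-reported kinetic values for human βB2-crystallin dimerization.

Coarse-grained simulation studies of the wild-type and doubly deamidated
(Q70E/Q162E) βB2-crystallin homodimer report mean first passage times
between the dissociated macrostate and the early dimeric macrostate. These
numbers serve as worked-example inputs for the fold-asymmetry calculation
and for protocol bookkeeping; they are inputs, not outputs, of this package.
"""

from __future__ import annotations

#: Reported MFPTs (ns) between the dissociated and early-dimer macrostates.
REPORTED_MFPT_NS = {
    "wt": {"association": 418.5, "dissociation": 520.7},
    "deamidated": {"association": 57.6, "dissociation": 1404.2},
}

#: Reported production protocol: replicas per system and length of each (ns).
REPORTED_PROTOCOL = {"n_replicas": 15, "replica_length_ns": 5000.0}


def fold_asymmetry(association_ns: float, dissociation_ns: float) -> float:
    """Ratio of the slower to the faster of two opposing MFPTs.

    A value of 1 means association and dissociation take equally long; the
    deamidated system's reported values give a ~24-fold asymmetry (binds
    fast, unbinds slowly).
    """
    if association_ns <= 0 or dissociation_ns <= 0:
        raise ValueError("MFPTs must be positive")
    pair = sorted([association_ns, dissociation_ns])
    return pair[1] / pair[0]
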