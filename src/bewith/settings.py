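"""The three published between/within settings.

Each setting turns a :class:`~bewith.mutnet.PairNetwork` into the
between/within weight functions and the constraint edge sets E_X (module
density) and E_Y (between-edge requirement):

=================  ======================  =======================  ====  ====
setting            within(i, j)            between(i, j)            E_X   E_Y
=================  ======================  =======================  ====  ====
BeME-WithFun       w_F                     w_ME - w_F               E_F   E_ME
BeME-WithCo        w_CO - w_ME             w_ME - w_CO              E_CO  E_ME
BeCo-WithMEFun     w_ME - w_CO + w_F       w_CO - w_ME - w_F        E_F   E_CO
=================  ======================  =======================  ====  ====

BeME-WithFun neither rewards nor penalizes mutual exclusivity inside a
module: w_ME enters only the between score.  For the latter two settings
within(i, j) = -between(i, j) identically.
"""

from __future__ import annotations

from .mutnet import PairNetwork, WeightFunctions

__all__ = ["beme_withfun", "beme_withco", "beco_withmefun", "get_setting",
           "SETTINGS", "co_test_for_setting"]


def _pairs(net: PairNetwork):
    return set(net.w_me) | set(net.w_co) | set(net.w_f)


def beme_withfun(net: PairNetwork) -> WeightFunctions:
    """Functionally coherent modules, mutually exclusive between modules."""
    between = {}
    within = {}
    for p in _pairs(net):
        f, me = net.w_f.get(p, 0.0), net.w_me.get(p, 0.0)
        if f:
            within[p] = f
        if me - f:
            between[p] = me - f
    return WeightFunctions(between_map=between, within_map=within,
                           e_x=net.e_f, e_y=net.e_me, name="beme-withfun")


def beme_withco(net: PairNetwork) -> WeightFunctions:
    """Co-occurring modules, mutually exclusive between modules."""
    between = {}
    within = {}
    for p in _pairs(net):
        me, co = net.w_me.get(p, 0.0), net.w_co.get(p, 0.0)
        if co - me:
            within[p] = co - me
            between[p] = me - co
    return WeightFunctions(between_map=between, within_map=within,
                           e_x=net.e_co, e_y=net.e_me, name="beme-withco")


def beco_withmefun(net: PairNetwork) -> WeightFunctions:
    """Mutually exclusive, functionally tied modules that co-occur pairwise."""
    between = {}
    within = {}
    for p in _pairs(net):
        me = net.w_me.get(p, 0.0)
        co = net.w_co.get(p, 0.0)
        f = net.w_f.get(p, 0.0)
        w = me - co + f
        if w:
            within[p] = w
            between[p] = -w
    return WeightFunctions(between_map=between, within_map=within,
                           e_x=net.e_f, e_y=net.e_co, name="beco-withmefun")


SETTINGS = {
    "beme-withfun": beme_withfun,
    "beme-withco": beme_withco,
    "beco-withmefun": beco_withmefun,
}

#: Co-occurrence test used to build E_CO per setting.  BeME-WithCo builds its
#: network with the hypergeometric test (the more permissive choice lets
#: mutagenic-process co-occurrence through; WeSCO remains available post hoc);
#: BeCo-WithMEFun defaults to the frequency-corrected WeSCO.
CO_TESTS = {
    "beme-withfun": "hypergeom",  # E_CO unused by the objective in this setting
    "beme-withco": "hypergeom",
    "beco-withmefun": "wesco",
}


def get_setting(name: str):
    try:
        return SETTINGS[name]
    except KeyError:
        raise ValueError(
            f"unknown setting {name!r}; choose from {sorted(SETTINGS)}"
        ) from None


def co_test_for_setting(name: str) -> str:
    return CO_TESTS.get(name, "hypergeom")
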