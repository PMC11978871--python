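"""Stochastic scanning-collision model of PKR activation on dsRNA.

The model embodies the mechanism that PKR activation requires two molecules
on the same duplex: free kinase binds dsRNA with a 15 bp footprint, scans by
1D diffusion, and when two PKR footprints collide each is trans-
autophosphorylated with a per-contact probability (a lone PKR never
autophosphorylates).  A second scanner (PACT) co-occupies duplexes with its
own kinetics; PKR-PACT collisions evict PKR with a configurable probability,
which both shortens PKR's residence and interrupts its search for a partner.

The simulator is a fixed-time-step kinetic Monte Carlo over discrete
molecules and duplexes: positions are continuous (bp) with hard-core
exclusion between footprints, binding is pseudo-first-order in the total
dsRNA molar concentration with the target duplex drawn uniformly and the
landing site uniform over the feasible gaps, and the free pools deplete as
molecules bind (this depletion produces the dispersal inhibition at excess
dsRNA).  The PKR and PACT random streams are independent children of the
master seed, so zeroing the PACT parameters leaves the PKR trajectory
bit-identical.

Default parameters demonstrate the model's qualitative regimes (length
ordering, biphasic dose response, inhibition without sequestration); they
are not fitted to any kinase-assay gel.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "KineticParams",
    "ActivationResult",
    "HeatmapSpec",
    "mass_to_molarity",
    "simulate_system",
    "activation_heatmap",
]

#: Average molar mass of one base pair of duplex RNA (g/mol/bp).
GRAMS_PER_MOL_PER_BP = 660.0


def mass_to_molarity(mass_conc_ng_ul: float, length_bp: float) -> float:
    """Convert a dsRNA mass concentration (ng/ul) to nM for a given length."""
    if mass_conc_ng_ul < 0 or length_bp <= 0:
        raise ValueError("mass concentration must be >= 0 and length > 0")
    return mass_conc_ng_ul * 1e6 / (length_bp * GRAMS_PER_MOL_PER_BP)


@dataclass(frozen=True)
class KineticParams:
    """Rates, footprints and discretization for the lattice simulator.

    ``*_k_on`` are per-nM per-s; ``*_k_off`` per-s; diffusion in bp^2/s.
    ``nm_per_molecule`` sets the molar concentration represented by one
    simulated molecule, tying discrete counts to the nM rate constants.
    ``contact_tol`` (bp) is the gap below which two footprints are "in
    contact".  The run refuses to start if any per-step event probability
    reaches 0.1 (fixed-step accuracy guard).
    """

    pkr_k_on: float = 0.001
    pkr_k_off: float = 0.25
    pkr_diffusion: float = 10000.0
    footprint: float = 15.0
    phospho_prob_per_contact: float = 0.05
    pact_k_on: float = 0.005
    pact_k_off: float = 5.0
    pact_diffusion: float = 5000.0
    pact_footprint: float = 15.0
    eviction_prob_on_contact: float = 0.9
    t_end: float = 15.0
    dt: float = 0.005
    contact_tol: float = 1.0
    nm_per_molecule: float = 2.5
    mutual_phospho: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pkr_k_on", "pkr_k_off", "pkr_diffusion", "pact_k_on",
                     "pact_k_off", "pact_diffusion"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        for name in ("phospho_prob_per_contact", "eviction_prob_on_contact"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0, 1]")
        if self.footprint < 1 or self.pact_footprint < 1:
            raise ValueError("footprints must be >= 1 bp")
        if self.dt <= 0 or self.t_end <= 0:
            raise ValueError("dt and t_end must be > 0")


@dataclass
class ActivationResult:
    """Time course of the phosphorylated PKR fraction plus diagnostics.

    ``pact_site_occupancy`` is the time-averaged fraction of PKR-binding
    sites (duplex_length // footprint per duplex) stably occupied by PACT;
    ``mean_pkr_per_occupied_duplex`` and ``cooccupancy_fraction`` (fraction
    of PKR-occupied duplexes that also carry >= 1 PACT) summarise the
    co-occupancy statistics the mechanism turns on.
    """

    times: np.ndarray
    phospho_fraction: np.ndarray
    n_pkr: int
    n_pact: int
    n_duplexes: int
    length: float
    pact_site_occupancy: float = 0.0
    mean_pkr_per_occupied_duplex: float = 0.0
    cooccupancy_fraction: float = 0.0

    @property
    def final_fraction(self) -> float:
        return float(self.phospho_fraction[-1])


@dataclass(frozen=True)
class HeatmapSpec:
    """Grid of duplex lengths x mass concentrations x PACT levels."""

    lengths_bp: tuple
    dsrna_ng_ul: tuple
    pact_nm: tuple
    replicates: int = 3
    n_pkr: int = 40
    base_params: KineticParams = field(default_factory=KineticParams)

    def __post_init__(self) -> None:
        if not (self.lengths_bp and self.dsrna_ng_ul and self.pact_nm):
            raise ValueError("heatmap axes must be non-empty")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")


def _resolve_excluded(order_pos, footprints, L):
    """Order-preserving hard-core projection of proposed positions.

    ``order_pos`` are proposed left edges in the occupants' current spatial
    order.  A left-to-right then right-to-left clamp keeps neighbours
    disjoint and inside [0, L - footprint]; crossings become contacts.
    """
    n = order_pos.size
    x = order_pos.copy()
    for i in range(n):
        lo = 0.0 if i == 0 else x[i - 1] + footprints[i - 1]
        x[i] = max(x[i], lo) if i > 0 else max(x[i], 0.0)
    for i in range(n - 1, -1, -1):
        hi = L - footprints[i] if i == n - 1 else x[i + 1] - footprints[i]
        x[i] = min(x[i], hi)
    for i in range(n):
        lo = 0.0 if i == 0 else x[i - 1] + footprints[i - 1]
        x[i] = max(x[i], lo)
    return x


def simulate_system(params: KineticParams,
                    length: float,
                    n_duplexes: int,
                    n_pkr: int,
                    n_pact: int = 0,
                    record_every: int = 20,
                    dsrna_nm: Optional[float] = None) -> ActivationResult:
    """Run the scanning-collision simulator for one condition.

    Free molecules bind any duplex with a feasible footprint-sized gap at
    pseudo-first-order rate ``k_on * c_sites`` where the binding-site molar
    concentration is ``c_dsRNA * floor(length / footprint)``; ``dsrna_nm``
    overrides the duplex concentration implied by ``n_duplexes *
    nm_per_molecule`` when the discrete duplex count would distort it.
    Bound molecules diffuse with hard-core exclusion and dissociate at
    ``k_off``.  A *new* contact between two PKR footprints
    phosphorylates the pair with ``phospho_prob_per_contact`` (trans only);
    a new PKR-PACT contact evicts the PKR with
    ``eviction_prob_on_contact``.  Phosphorylated PKR keeps binding and
    scanning; there is no dephosphorylation, so the phospho fraction is
    non-decreasing.
    """
    p = params
    if length < p.footprint:
        # duplex cannot hold even one PKR: nothing ever binds
        n_steps = max(1, int(round(p.t_end / p.dt)))
        times = np.arange(0, n_steps + 1, record_every) * p.dt
        return ActivationResult(times=times,
                                phospho_fraction=np.zeros(times.size),
                                n_pkr=n_pkr, n_pact=n_pact,
                                n_duplexes=n_duplexes, length=length)
    # association is per binding *site*: a duplex of length L presents
    # floor(L / footprint) sites, so at matched mass the total binding flux
    # is length-independent while occupancy concentrates on fewer duplexes
    # for long dsRNA (the co-occupancy effect the mechanism turns on)
    sites_per_duplex = max(1.0, length // p.footprint)
    c_ds = n_duplexes * p.nm_per_molecule if dsrna_nm is None else dsrna_nm
    c_sites = c_ds * sites_per_duplex
    probs = {
        "pkr bind": p.pkr_k_on * c_sites * p.dt,
        "pkr off": p.pkr_k_off * p.dt,
        "pact bind": p.pact_k_on * c_sites * p.dt,
        "pact off": p.pact_k_off * p.dt,
    }
    for what, pr in probs.items():
        if what.startswith("pkr") and n_pkr == 0:
            continue
        if what.startswith("pact") and n_pact == 0:
            continue
        if pr >= 0.1:
            raise ValueError(
                f"dt too coarse: per-step {what} probability {pr:.3f} >= 0.1")
    ss = np.random.SeedSequence(p.rng_seed)
    rng_pkr, rng_pact = [np.random.default_rng(s) for s in ss.spawn(2)]

    n_total = n_pkr + n_pact
    is_pkr = np.zeros(n_total, dtype=bool)
    is_pkr[:n_pkr] = True
    fp = np.where(is_pkr, p.footprint, p.pact_footprint)
    diff_sd = np.where(is_pkr, np.sqrt(2 * p.pkr_diffusion * p.dt),
                       np.sqrt(2 * p.pact_diffusion * p.dt))
    bound = np.zeros(n_total, dtype=bool)
    duplex = np.full(n_total, -1, dtype=int)
    pos = np.full(n_total, np.nan)
    phospho = np.zeros(n_total, dtype=bool)

    occupants: dict[int, list[int]] = {}
    contacts: set[tuple[int, int]] = set()

    n_steps = max(1, int(round(p.t_end / p.dt)))
    rec_t = [0.0]
    rec_f = [0.0]
    pact_occ_acc = 0.0
    coocc_acc = 0.0
    coocc_n = 0
    pkr_per_dup_acc = 0.0
    pkr_per_dup_n = 0

    def _bind(mol: int, rng: np.random.Generator) -> None:
        d = int(rng.integers(n_duplexes))
        occ = occupants.get(d, [])
        # feasible left-edge segments between occupants
        segs = []
        prev = 0.0
        for j in sorted(occ, key=lambda m: pos[m]):
            hi = pos[j] - fp[mol]
            if hi >= prev:
                segs.append((prev, hi))
            prev = pos[j] + fp[j]
        hi = length - fp[mol]
        if hi >= prev:
            segs.append((prev, hi))
        if not segs:
            return
        lengths = np.array([h - l for l, h in segs])
        total = lengths.sum()
        if total == 0:
            lo = segs[int(rng.integers(len(segs)))][0]
        else:
            u = rng.uniform(0.0, total)
            lo = segs[-1][1]
            for (l, h), w in zip(segs, lengths):
                if u <= w:
                    lo = l + u
                    break
                u -= w
        bound[mol] = True
        duplex[mol] = d
        pos[mol] = lo
        occupants.setdefault(d, []).append(mol)

    def _unbind(mol: int) -> None:
        d = duplex[mol]
        occupants[d].remove(mol)
        if not occupants[d]:
            del occupants[d]
        bound[mol] = False
        duplex[mol] = -1
        pos[mol] = np.nan

    for step in range(1, n_steps + 1):
        # --- diffusion with exclusion, per occupied duplex
        new_contacts: set[tuple[int, int]] = set()
        for d, occ in list(occupants.items()):
            if len(occ) == 1:
                m = occ[0]
                rng = rng_pkr if is_pkr[m] else rng_pact
                x = pos[m] + rng.normal(0.0, diff_sd[m])
                Lm = length - fp[m]
                x = abs(x) if x < 0 else x
                x = np.mod(x, 2 * Lm) if Lm > 0 else 0.0
                pos[m] = Lm - abs(Lm - x) if Lm > 0 else 0.0
                continue
            order = sorted(occ, key=lambda m: pos[m])
            prop = np.array([
                pos[m] + (rng_pkr if is_pkr[m] else rng_pact)
                .normal(0.0, diff_sd[m]) for m in order])
            # keep spatial order before clamping (reflect crossings at contact)
            prop = np.sort(prop)
            fps = np.array([fp[m] for m in order])
            newx = _resolve_excluded(prop, fps, length)
            for m, x in zip(order, newx):
                pos[m] = x
            for a, b in zip(order[:-1], order[1:]):
                if pos[b] - (pos[a] + fp[a]) <= p.contact_tol:
                    new_contacts.add((min(a, b), max(a, b)))
        # --- contact-triggered reactions (on newly formed contacts only)
        evicted: list[int] = []
        for pair in new_contacts - contacts:
            a, b = pair
            if is_pkr[a] and is_pkr[b]:
                if rng_pkr.uniform() < p.phospho_prob_per_contact:
                    phospho[a] = True
                    if p.mutual_phospho:
                        phospho[b] = True
            else:
                pk = a if is_pkr[a] else b
                if rng_pact.uniform() < p.eviction_prob_on_contact:
                    evicted.append(pk)
        for m in set(evicted):
            if bound[m]:
                _unbind(m)
        contacts = {c for c in new_contacts
                    if bound[c[0]] and bound[c[1]]}
        # --- dissociation
        for m in np.flatnonzero(bound):
            rng = rng_pkr if is_pkr[m] else rng_pact
            pr = probs["pkr off"] if is_pkr[m] else probs["pact off"]
            if pr > 0 and rng.uniform() < pr:
                _unbind(m)
        contacts = {c for c in contacts if bound[c[0]] and bound[c[1]]}
        # --- binding from the free pools
        for m in np.flatnonzero(~bound):
            rng = rng_pkr if is_pkr[m] else rng_pact
            pr = probs["pkr bind"] if is_pkr[m] else probs["pact bind"]
            if pr > 0 and rng.uniform() < pr:
                _bind(m, rng)
        # --- diagnostics + recording
        n_pact_bound = int(np.sum(bound & ~is_pkr))
        pact_occ_acc += n_pact_bound / (n_duplexes * sites_per_duplex)
        pkr_dups = {duplex[m] for m in np.flatnonzero(bound & is_pkr)}
        if pkr_dups:
            pkr_per_dup_acc += sum(
                sum(1 for m in occupants[d] if is_pkr[m]) for d in pkr_dups
            ) / len(pkr_dups)
            pkr_per_dup_n += 1
            pact_dups = {duplex[m] for m in np.flatnonzero(bound & ~is_pkr)}
            coocc_acc += len(pkr_dups & pact_dups) / len(pkr_dups)
            coocc_n += 1
        if step % record_every == 0 or step == n_steps:
            rec_t.append(step * p.dt)
            rec_f.append(float(np.sum(phospho)) / max(n_pkr, 1))

    return ActivationResult(
        times=np.array(rec_t), phospho_fraction=np.array(rec_f),
        n_pkr=n_pkr, n_pact=n_pact, n_duplexes=n_duplexes, length=length,
        pact_site_occupancy=pact_occ_acc / n_steps,
        mean_pkr_per_occupied_duplex=(
            pkr_per_dup_acc / pkr_per_dup_n if pkr_per_dup_n else 0.0),
        cooccupancy_fraction=coocc_acc / coocc_n if coocc_n else 0.0)


def activation_heatmap(spec: HeatmapSpec) -> pd.DataFrame:
    """Endpoint phospho fraction over the length x concentration x PACT grid.

    Returns one row per grid cell with the replicate mean and SD of the final
    phosphorylated fraction plus co-occupancy diagnostics.  Molecule counts
    derive from the nM axes through ``nm_per_molecule`` (at least one duplex
    per condition).
    """
    p0 = spec.base_params
    rows = []
    ss = np.random.SeedSequence(p0.rng_seed)
    seeds = iter(ss.generate_state(
        len(spec.lengths_bp) * len(spec.dsrna_ng_ul) * len(spec.pact_nm)
        * spec.replicates) >> 1)
    for L, ng, pact in itertools.product(spec.lengths_bp, spec.dsrna_ng_ul,
                                         spec.pact_nm):
        c_ds = mass_to_molarity(ng, L)
        n_dup = max(1, int(round(c_ds / p0.nm_per_molecule)))
        n_pact = int(round(pact / p0.nm_per_molecule))
        finals, occs, cooccs, per_dup = [], [], [], []
        for _ in range(spec.replicates):
            params = replace(p0, rng_seed=int(next(seeds)))
            res = simulate_system(params, L, n_dup, spec.n_pkr, n_pact,
                                  dsrna_nm=c_ds)
            finals.append(res.final_fraction)
            occs.append(res.pact_site_occupancy)
            cooccs.append(res.cooccupancy_fraction)
            per_dup.append(res.mean_pkr_per_occupied_duplex)
        rows.append({
            "length_bp": L, "ds_ng_ul": ng, "pact_nM": pact,
            "mean_activation": float(np.mean(finals)),
            "sd_activation": float(np.std(finals, ddof=1))
            if len(finals) > 1 else 0.0,
            "pact_site_occupancy": float(np.mean(occs)),
            "cooccupancy_fraction": float(np.mean(cooccs)),
            "mean_pkr_per_occupied_duplex": float(np.mean(per_dup)),
        })
    return pd.DataFrame(rows)
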