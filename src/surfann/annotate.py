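"""MS2 annotation: spectrum graph, ion ladders, lipid anchor, family call.

The reconstruction mirrors how cyclic-lipopeptide CID spectra are read by
hand. Peaks become nodes of a directed acyclic *spectrum graph* whose edges
connect peaks separated by one amino-acid residue mass; a b-type ladder is a
path in this graph. The lowest b rung is not a bare residue sum: it carries
the fatty-acyl moiety, so ``first rung - proton - (assumed prefix residues)``
must land on the lipid homolog series — this *lipid anchor* both yields the
acyl carbon count n and distinguishes a genuine b ladder from chains that
merely look ladder-like (e.g. paths that wander through y-type peaks).

Absolute y-type values in the targeted data behave as plain suffix residue
sums (not proton+water conventions), so y rungs complement b rungs almost
exactly: b + y ~ precursor. Complements are reported as a confidence feature
and never veto an annotation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, NamedTuple, Sequence

import networkx as nx

from .config import FamilyTemplate, PipelineConfig
from .exceptions import DomainError, InconsistencyError
from .masses import (
    AdductTable,
    ChainMatch,
    LipidSeries,
    ResidueMassTable,
    ResidueMatch,
)
from .series import NeutralLossMatch, find_neutral_loss
from .spectra import Spectrum

UNASSIGNED = "unassigned"


@dataclass(frozen=True)
class IonLadder:
    """An ordered chain of peaks whose gaps each match a residue mass.

    ``steps[i]`` is the candidate set (best first) for the gap between
    ``rungs[i]`` and ``rungs[i+1]``.
    """

    ion_type: str | None  # "b", "y", or None for an empty ladder
    rungs: tuple[float, ...] = ()
    steps: tuple[tuple[ResidueMatch, ...], ...] = ()
    total_intensity: float = 0.0

    def __post_init__(self) -> None:
        if self.rungs and self.steps and len(self.steps) != len(self.rungs) - 1:
            # steps may be omitted entirely (bare rung chain), but when
            # present there must be exactly one candidate set per gap
            raise DomainError("steps must have length len(rungs) - 1")
        if any(b <= a for a, b in zip(self.rungs, self.rungs[1:])):
            raise DomainError("rungs must be strictly ascending")

    def __len__(self) -> int:
        return len(self.rungs)

    @property
    def step_errors(self) -> tuple[float, ...]:
        """Best-candidate absolute error per step."""
        return tuple(s[0].error for s in self.steps)


class TerminalAssignment(NamedTuple):
    """Residue closing the ring: precursor minus the top ladder rung."""

    delta: float
    candidates: tuple[ResidueMatch, ...]


class ComplementPair(NamedTuple):
    """A b/y rung pair summing to the precursor within tolerance."""

    b_mz: float
    y_mz: float
    sum_error: float


@dataclass(frozen=True)
class FamilyCall:
    """Outcome of template classification."""

    family: str
    matched_positions: int = 0
    failures: tuple[str, ...] = ()
    ambiguous_positions: tuple[int, ...] = ()


@dataclass(frozen=True)
class LipopeptideAnnotation:
    """The end product of annotating one MS2 spectrum."""

    precursor_mz: float
    sequence: tuple[tuple[str, ...], ...]  # candidate labels per position, best first
    assumed_positions: tuple[int, ...]  # 1-based positions filled from the template
    chain_length: int | None
    lipid_error: float | None
    family: str
    complement_checks: tuple[ComplementPair, ...]
    score: float
    b_ladder: IonLadder
    y_ladder: IonLadder
    terminal: TerminalAssignment | None
    water_loss: dict[str, NeutralLossMatch | None] = field(default_factory=dict)
    classification: FamilyCall | None = None
    retention_time: float | None = None
    source_id: str = ""

    def to_dict(self) -> dict:
        def ladder(l: IonLadder) -> dict:
            return {
                "ion_type": l.ion_type,
                "rungs": list(l.rungs),
                "steps": [
                    [{"symbol": c.symbol, "error": c.error} for c in s] for s in l.steps
                ],
                "total_intensity": l.total_intensity,
            }

        return {
            "precursor_mz": self.precursor_mz,
            "rt": self.retention_time,
            "source_id": self.source_id,
            "family": self.family,
            "chain_length": self.chain_length,
            "lipid_error": self.lipid_error,
            "score": self.score,
            "sequence": [list(p) for p in self.sequence],
            "assumed_positions": list(self.assumed_positions),
            "terminal": None
            if self.terminal is None
            else {
                "delta": self.terminal.delta,
                "candidates": [
                    {"symbol": c.symbol, "error": c.error} for c in self.terminal.candidates
                ],
            },
            "complements": [
                {"b_mz": c.b_mz, "y_mz": c.y_mz, "sum_error": c.sum_error}
                for c in self.complement_checks
            ],
            "water_loss": {
                k: (None if v is None else {"mz": v.mz, "error": v.error})
                for k, v in self.water_loss.items()
            },
            "b_ladder": ladder(self.b_ladder),
            "y_ladder": ladder(self.y_ladder),
        }


# ---------------------------------------------------------------------------
# Spectrum graph
# ---------------------------------------------------------------------------


def build_spectrum_graph(
    spectrum: Spectrum,
    tol: float,
    table: ResidueMassTable | None = None,
    adducts: AdductTable = AdductTable(),
    precursor_window: float = 2.0,
) -> nx.DiGraph:
    """Directed acyclic graph over peaks with residue-labelled edges.

    An edge u -> v (u < v in m/z) exists iff ``v - u`` matches some residue
    mass within ``tol``; the edge attribute ``candidates`` holds the ranked
    :class:`ResidueMatch` set. Peaks within ``precursor_window`` of the
    precursor or of precursor - H2O are excluded: molecular-ion and
    dehydration peaks are not sequence rungs and would otherwise extend every
    ladder spuriously.
    """
    if not tol > 0:
        raise DomainError("tol must be positive")
    table = table or _default_table()
    masses = table.labels.values()
    lo, hi = min(masses) - tol, max(masses) + tol

    excluded_centres = []
    if spectrum.precursor_mz is not None:
        excluded_centres = [
            spectrum.precursor_mz,
            spectrum.precursor_mz - adducts.water_mass,
        ]
    graph = nx.DiGraph()
    nodes = [
        p
        for p in spectrum.peaks
        if not any(abs(p.mz - c) <= precursor_window for c in excluded_centres)
    ]
    for p in nodes:
        graph.add_node(p.mz, intensity=p.intensity)
    for i, u in enumerate(nodes):
        for v in nodes[i + 1 :]:
            delta = v.mz - u.mz
            if delta > hi:
                break
            if delta < lo:
                continue
            candidates = table.match(delta, tol)
            if candidates:
                graph.add_edge(u.mz, v.mz, candidates=tuple(candidates))
    return graph


def _default_table() -> ResidueMassTable:
    from .masses import default_table

    return default_table()


def _path_intensity(graph: nx.DiGraph, path: Sequence[float]) -> float:
    return sum(graph.nodes[m]["intensity"] for m in path)


def _ladder_from_path(
    graph: nx.DiGraph, path: Sequence[float], ion_type: str | None
) -> IonLadder:
    steps = tuple(graph.edges[u, v]["candidates"] for u, v in zip(path, path[1:]))
    return IonLadder(
        ion_type=ion_type,
        rungs=tuple(path),
        steps=steps,
        total_intensity=_path_intensity(graph, path),
    )


def extract_ladder(graph: nx.DiGraph, strategy: str = "longest") -> IonLadder:
    """The best path through the spectrum graph.

    ``"longest"`` (the only strategy): most rungs, ties broken by greater
    total intensity, then by lower starting m/z, then lexicographically —
    fully deterministic. An empty or edgeless graph yields an empty ladder.
    """
    if strategy != "longest":
        raise ValueError(f"unknown ladder strategy {strategy!r}")
    best: tuple | None = None
    # DP over nodes in ascending m/z (a topological order of this DAG).
    state: dict[float, tuple] = {}
    for v in sorted(graph.nodes):
        w = graph.nodes[v]["intensity"]
        cand = (1, w, -v, (v,))
        for u in graph.predecessors(v):
            lu, iu, su, pu = state[u]
            c = (lu + 1, iu + w, su, pu + (v,))
            cand = max(cand, c, key=_path_key)
        state[v] = cand
        if cand[0] >= 2 and (best is None or _path_key(cand) > _path_key(best)):
            best = cand
    if best is None:
        return IonLadder(ion_type=None)
    return _ladder_from_path(graph, best[3], None)


def _path_key(s: tuple) -> tuple:
    length, intensity, neg_start, path = s
    return (length, intensity, neg_start, tuple(-m for m in path))


def enumerate_maximal_paths(graph: nx.DiGraph, limit: int = 50_000) -> list[tuple[float, ...]]:
    """All maximal (inextensible) paths with at least 2 rungs, sorted."""
    roots = [n for n in graph.nodes if graph.in_degree(n) == 0 and graph.out_degree(n) > 0]
    out: list[tuple[float, ...]] = []

    def extend(path: list[float]) -> None:
        if len(out) >= limit:
            return
        nxt = list(graph.successors(path[-1]))
        if not nxt:
            if len(path) >= 2:
                out.append(tuple(path))
            return
        for v in sorted(nxt):
            extend(path + [v])

    for r in sorted(roots):
        extend([r])
    return sorted(out)


# ---------------------------------------------------------------------------
# Ladder interpretation
# ---------------------------------------------------------------------------


def assign_terminal_residue(
    precursor_mz: float,
    ladder: IonLadder,
    tol: float,
    table: ResidueMassTable | None = None,
) -> TerminalAssignment:
    """Residue spanned between the top ladder rung and the precursor.

    ``delta = precursor_mz - max(rungs)``; an empty candidate set is a valid
    result (unassigned ring-closing terminus).
    """
    if not ladder.rungs:
        raise DomainError("cannot assign a terminal residue from an empty ladder")
    table = table or _default_table()
    delta = precursor_mz - ladder.rungs[-1]
    if delta <= 0:
        return TerminalAssignment(delta, ())
    return TerminalAssignment(delta, tuple(table.match(delta, tol)))


def infer_lipid_anchor(
    ladder: IonLadder,
    assigned_prefix: Sequence[str],
    anchor_tol: float,
    table: ResidueMassTable | None = None,
    lipid_series: LipidSeries = LipidSeries(),
    adducts: AdductTable = AdductTable(),
) -> ChainMatch | None:
    """Acyl carbon count from the lowest b rung.

    ``residual = first rung - proton - sum(assigned_prefix residue masses)``
    is matched against the lipid series; ``None`` when nothing lies within
    ``anchor_tol``. A non-positive residual means the prefix hypothesis is
    impossible and raises :class:`InconsistencyError`.
    """
    if not ladder.rungs:
        raise DomainError("cannot anchor an empty ladder")
    table = table or _default_table()
    residual = ladder.rungs[0] - adducts.proton_mass - sum(table.mass(s) for s in assigned_prefix)
    if residual <= 0:
        raise InconsistencyError(
            f"first rung {ladder.rungs[0]:.3f} cannot contain proton + prefix "
            f"{list(assigned_prefix)} (residual {residual:.3f} Da)"
        )
    return lipid_series.chain_length_from_mass(residual, anchor_tol)


def reconcile_complements(
    precursor_mz: float,
    b_ladder: IonLadder,
    y_ladder: IonLadder,
    comp_tol: float,
) -> list[ComplementPair]:
    """b/y rung pairs with ``|b + y - precursor| <= comp_tol`` (signed errors).

    A confidence feature only; never used to veto an annotation.
    """
    if not comp_tol > 0:
        raise DomainError("comp_tol must be positive")
    pairs = []
    for y in y_ladder.rungs:
        best = None
        for b in b_ladder.rungs:
            err = b + y - precursor_mz
            if abs(err) <= comp_tol and (best is None or abs(err) < abs(best[1])):
                best = (b, err)
        if best is not None:
            pairs.append(ComplementPair(best[0], y, best[1]))
    return pairs


def classify_family(
    sequence: Sequence[Iterable[str]],
    chain_length: int | None,
    templates: dict[str, FamilyTemplate],
) -> FamilyCall:
    """Match candidate sets and chain length against the template registry.

    A (complete) template matches when every constrained position's allowed
    set intersects that position's candidate set and the chain length lies in
    the template's lipid range. Among matching templates the one whose
    residues are most often the *best* candidate wins.
    """
    position_sets = [tuple(p) for p in sequence]
    ambiguous = tuple(i + 1 for i, p in enumerate(position_sets) if len(p) > 1)
    matches: list[tuple[int, str]] = []
    failures: list[str] = []
    for name, tpl in sorted(templates.items()):
        if not tpl.is_complete:
            continue
        if len(position_sets) != tpl.length:
            failures.append(f"{name}: sequence length {len(position_sets)} != {tpl.length}")
            continue
        if chain_length is None or not (tpl.lipid_range[0] <= chain_length <= tpl.lipid_range[1]):
            failures.append(f"{name}: chain length {chain_length} outside {tpl.lipid_range}")
            continue
        ok = True
        exact_best = 0
        for i, allowed in enumerate(tpl.positions):
            cands = position_sets[i]
            if not (allowed & set(cands)):
                failures.append(
                    f"{name}: position {i + 1} requires one of {sorted(allowed)}, "
                    f"candidates {list(cands)}"
                )
                ok = False
                break
            if cands and cands[0] in allowed:
                exact_best += 1
        if ok:
            matches.append((exact_best, name))
    if not matches:
        return FamilyCall(UNASSIGNED, failures=tuple(failures), ambiguous_positions=ambiguous)
    exact_best, name = max(matches, key=lambda t: (t[0], t[1]))
    return FamilyCall(
        name, matched_positions=exact_best, failures=(), ambiguous_positions=ambiguous
    )


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _Interpretation:
    template: FamilyTemplate
    rungs: tuple[float, ...]
    steps: tuple[tuple[ResidueMatch, ...], ...]
    prefix: tuple[str, ...]
    terminal: TerminalAssignment
    anchor: ChainMatch | None
    score: float  # joint: b ladder + anchored y-ladder bonus
    y_ladder: "IonLadder"
    intensity: float

    @property
    def sort_key(self) -> tuple:
        return (
            self.anchor is not None,
            self.score,
            len(self.rungs),
            self.intensity,
            -self.rungs[0],
            tuple(-m for m in self.rungs),
        )


def _score(
    steps: Sequence[tuple[ResidueMatch, ...]],
    terminal: TerminalAssignment,
    anchor: ChainMatch | None,
    error_weight: float,
) -> float:
    """Observed assignments minus weighted total supporting mass error.

    Coverage counts only positions read off the spectrum (ladder steps and,
    when matched, the ring-closing terminal residue); template-assumed prefix
    positions earn nothing. Each claimed assignment is taxed by its absolute
    mass error (Da) times ``error_weight``, and a matched lipid anchor
    contributes its own |error| to the tax. With the default weight 1.5 one
    extra claimed position (+1) cannot pay for a near-tolerance (~1 Da)
    supporting error, which is what separates a genuine acyl-anchored b
    ladder from longer chains that drift through y-type peaks.
    """
    errors = [s[0].error for s in steps]
    coverage = len(steps)
    if terminal.candidates:
        coverage += 1
        errors.append(terminal.candidates[0].error)
    if anchor is not None:
        errors.append(abs(anchor.error))
    return coverage - error_weight * sum(errors)


def _suffix_sums(tpl: FamilyTemplate, table: ResidueMassTable) -> dict[int, float]:
    masses = [table.mass(tpl.representative(i)) for i in range(tpl.length)]
    return {k: sum(masses[-k:]) for k in range(1, tpl.length)}


def _anchored_y_score(
    y_ladder: "IonLadder",
    tpl: FamilyTemplate,
    table: ResidueMassTable,
    anchor_tol: float,
    error_weight: float,
) -> float:
    """Bonus for a leftover chain that genuinely reads as a y-type ladder.

    y rungs behave as plain suffix residue sums, so a real y ladder's
    absolute rungs must track the template's suffix-sum sequence (each rung
    within the anchor tolerance of consecutive suffix lengths). Chains that
    merely look ladder-like (stray b rungs, decoy runs) fail this and earn
    nothing. This is the asymmetry that lets the winning interpretation be
    the one explaining the spectrum as b ladder *plus* complementary y
    ladder, rather than the chain with the most rungs.
    """
    if len(y_ladder) < 2:
        return 0.0
    sums = _suffix_sums(tpl, table)
    k0 = min(sums, key=lambda k: abs(y_ladder.rungs[0] - sums[k]))
    anchor_err = y_ladder.rungs[0] - sums[k0]
    if abs(anchor_err) > anchor_tol:
        return 0.0
    for i, rung in enumerate(y_ladder.rungs[1:], start=1):
        k = k0 + i
        if k not in sums or abs(rung - sums[k]) > anchor_tol:
            return 0.0
    errors = [s[0].error for s in y_ladder.steps] + [abs(anchor_err)]
    return (len(y_ladder.steps) + 1) - error_weight * sum(errors)


def _empty_annotation(ms2: Spectrum, length: int) -> LipopeptideAnnotation:
    return LipopeptideAnnotation(
        precursor_mz=ms2.precursor_mz,
        sequence=tuple(() for _ in range(length)),
        assumed_positions=(),
        chain_length=None,
        lipid_error=None,
        family=UNASSIGNED,
        complement_checks=(),
        score=0.0,
        b_ladder=IonLadder(ion_type=None),
        y_ladder=IonLadder(ion_type=None),
        terminal=None,
        retention_time=ms2.retention_time,
        source_id=ms2.source_id,
    )


def annotate_spectrum(ms2: Spectrum, config: PipelineConfig | None = None) -> LipopeptideAnnotation:
    """Full annotation of one MS2 spectrum.

    Pipeline: spectrum graph -> candidate b ladders (maximal paths and their
    suffixes, since leading rungs may belong to the complementary y series)
    -> per-template interpretation with terminal residue, lipid anchor, and
    the y ladder extracted from the unconsumed peaks -> the interpretation
    with a valid (template-range) anchor and the best joint score (b ladder
    plus suffix-sum-anchored y bonus; ties toward more rungs, then
    intensity, then lower start) wins -> complement reconciliation ->
    family classification.

    A spectrum yielding no ladder returns a valid annotation with family
    ``"unassigned"`` and empty ladders.
    """
    config = config or PipelineConfig()
    if ms2.precursor_mz is None:
        raise DomainError("annotate_spectrum requires a precursor m/z")
    table = config.residue_table()
    lipid = config.lipid_series()
    adducts = config.adducts()
    templates = config.templates()
    complete = [t for _, t in sorted(templates.items()) if t.is_complete]

    graph = build_spectrum_graph(
        ms2, config.step_tol, table, adducts, config.precursor_window
    )
    paths = enumerate_maximal_paths(graph)
    candidate_rungs = sorted({p[k:] for p in paths for k in range(len(p) - 1)})

    interpretations: list[_Interpretation] = []
    for tpl in complete:
        for rungs in candidate_rungs:
            n_steps = len(rungs) - 1
            prefix_len = tpl.length - n_steps - 1
            if prefix_len < 0:
                continue
            ladder = _ladder_from_path(graph, rungs, "b")
            terminal = assign_terminal_residue(ms2.precursor_mz, ladder, config.step_tol, table)
            prefix = tuple(tpl.representative(i) for i in range(prefix_len))
            try:
                anchor = infer_lipid_anchor(
                    ladder, prefix, config.anchor_tol, table, lipid, adducts
                )
            except InconsistencyError:
                anchor = None
            if anchor is not None and not (
                tpl.lipid_range[0] <= anchor.n <= tpl.lipid_range[1]
            ):
                # an acyl count impossible for this family is no anchor at all
                anchor = None
            y_graph = graph.subgraph(n for n in graph.nodes if n not in set(rungs)).copy()
            y_best = extract_ladder(y_graph)
            y_ladder = (
                IonLadder("y", y_best.rungs, y_best.steps, y_best.total_intensity)
                if y_best.rungs
                else IonLadder(ion_type=None)
            )
            score = _score(
                ladder.steps, terminal, anchor, config.score_error_weight
            ) + _anchored_y_score(
                y_ladder, tpl, table, config.anchor_tol, config.score_error_weight
            )
            interpretations.append(
                _Interpretation(
                    template=tpl,
                    rungs=rungs,
                    steps=ladder.steps,
                    prefix=prefix,
                    terminal=terminal,
                    anchor=anchor,
                    score=score,
                    y_ladder=y_ladder,
                    intensity=ladder.total_intensity,
                )
            )

    if not interpretations:
        return _empty_annotation(ms2, config.peptide_length)

    winner = max(interpretations, key=lambda it: it.sort_key)
    b_ladder = _ladder_from_path(graph, winner.rungs, "b")
    y_ladder = winner.y_ladder

    complements = reconcile_complements(ms2.precursor_mz, b_ladder, y_ladder, config.comp_tol)

    water_loss = {
        "precursor": find_neutral_loss(
            ms2, ms2.precursor_mz, adducts.water_mass, config.loss_tol
        ),
        "top_rung": find_neutral_loss(
            ms2, b_ladder.rungs[-1], adducts.water_mass, config.loss_tol
        ),
    }

    # Candidate labels per position: assumed prefix, ladder steps, terminal.
    sequence: list[tuple[str, ...]] = [(s,) for s in winner.prefix]
    sequence += [tuple(c.symbol for c in step) for step in winner.steps]
    sequence.append(tuple(c.symbol for c in winner.terminal.candidates))
    assumed = tuple(range(1, len(winner.prefix) + 1))

    chain = winner.anchor.n if winner.anchor else None
    call = classify_family(sequence, chain, templates)

    return LipopeptideAnnotation(
        precursor_mz=ms2.precursor_mz,
        sequence=tuple(sequence),
        assumed_positions=assumed,
        chain_length=chain,
        lipid_error=winner.anchor.error if winner.anchor else None,
        family=call.family,
        complement_checks=tuple(complements),
        score=winner.score,
        b_ladder=b_ladder,
        y_ladder=y_ladder,
        terminal=winner.terminal,
        water_loss=water_loss,
        classification=call,
        retention_time=ms2.retention_time,
        source_id=ms2.source_id,
    )
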