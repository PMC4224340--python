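"""The folate pterin-branch case study as an executable fixture.

Ships the Amorphea species tree, the per-taxon architecture profiles of
the pterin-branch genes (folB/DHNA, folK/HPPK, folP/DHPS), a eukaryote-
wide architecture table, and the narrative per-branch event scenario whose
classification yields the headline counts: nine fissions in total, four by
open-reading-frame separation and five by loss of folB domains, one
tandem folB duplication on the opisthokont stem, one contraction of the
standalone tandem folB, and three whole-pathway losses.

Notes on fixture scope: the long-branch microsporidian (which also carries
the triple fusion) is excluded; the animal folB-folK gene of likely
prokaryotic origin is kept out of the Amorphea parsimony fixture but
retained in the eukaryote-wide table, where it contributes one of the four
fused architectures; ambiguous animal folB fragments are excluded
entirely; representative placeholder tips (``Metazoa_rep`` etc.) stand in
for clades whose exact sampled membership is a figure-level detail.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

from .distance import DEFAULT_MAX_COST
from .formats import read_profiles, read_scenario
from .model import DEFAULT_COSTS, CostModel, Profile, parse_profile
from .parsimony import count_by_type, extract_events, sankoff
from .scenario import Scenario, summarize_scenario, validate_scenario
from .treeio import Phylogeny, read_newick


@dataclass
class FolateFixture:
    amorphea_tree: Phylogeny
    amorphea_tips: dict[str, Profile]
    narrative_scenario: Scenario
    eukaryote_table: dict[str, Profile]
    notes: dict[str, str]


def _data_text(name: str) -> str:
    return resources.files("archevo.data").joinpath(name).read_text()


def folate_fixture() -> FolateFixture:
    """Load the folate case-study fixture from the packaged plain-text files."""
    import io

    import pandas as pd

    tree = read_newick(_data_text("amorphea.nwk"))
    with resources.as_file(resources.files("archevo.data").joinpath("amorphea_profiles.tsv")) as p:
        tips = read_profiles(p)
    with resources.as_file(resources.files("archevo.data").joinpath("eukaryote_profiles.tsv")) as p:
        table = read_profiles(p)
    with resources.as_file(resources.files("archevo.data").joinpath("folate_scenario.tsv")) as p:
        scenario = read_scenario(p, label="folate pterin-branch narrative scenario")
    notes = {}
    for name in ("amorphea_profiles.tsv", "eukaryote_profiles.tsv"):
        df = pd.read_csv(io.StringIO(_data_text(name)), sep="\t").fillna("")
        for _, row in df.iterrows():
            notes[row["taxon"]] = row.get("note", "")
    return FolateFixture(tree, tips, scenario, table, notes)


def run_case_study(
    mode: str = "annotate",
    root_constrained: bool = False,
    costs: CostModel = DEFAULT_COSTS,
    universe_depth: int = 2,
    max_mprs: int = 256,
    max_cost: float = DEFAULT_MAX_COST,
) -> dict:
    """One-command reproduction of the case-study numbers.

    ``annotate``: validate the narrative scenario against the tree and tip
    profiles and report per-type event counts.  ``infer``: run Sankoff
    parsimony (optionally with the root constrained to the triple-fusion
    profile) and report the minimal cost, the optimal root states, whether
    the triple fusion is among them, and how the optimum compares with the
    scenario's cost.
    """
    fx = folate_fixture()
    if mode == "annotate":
        report = validate_scenario(fx.amorphea_tree, fx.narrative_scenario, fx.amorphea_tips)
        summary = summarize_scenario(fx.amorphea_tree, fx.narrative_scenario, costs)
        return {
            "mode": "annotate",
            "scenario_valid": report.valid,
            "tip_mismatches": report.tip_mismatches,
            "grammar_errors": report.grammar_errors,
            "counts": summary.counts,
            "n_events": summary.n_events,
            "scenario_cost": summary.total_cost,
        }
    if mode != "infer":
        raise ValueError(f"unknown mode {mode!r} (expected 'annotate' or 'infer')")
    root_constraint = parse_profile("B-K-P") if root_constrained else None
    result = sankoff(
        fx.amorphea_tree,
        fx.amorphea_tips,
        costs,
        root_constraint=root_constraint,
        max_mprs=max_mprs,
        universe_depth=universe_depth,
        max_cost=max_cost,
    )
    summary = summarize_scenario(fx.amorphea_tree, fx.narrative_scenario, costs)
    triple = parse_profile("B-K-P")
    per_mpr_counts = [
        count_by_type(extract_events(rec)) for rec in result.reconstructions[:32]
    ]
    return {
        "mode": "infer",
        "root_constrained": root_constrained,
        "min_cost": result.total_cost,
        "scenario_cost": summary.total_cost,
        "cost_gap_strict": bool(result.total_cost < summary.total_cost - 1e-9),
        "optimal_root_profiles": [p.text for p in result.optimal_root_profiles],
        "triple_fusion_root_optimal": triple in result.optimal_root_profiles,
        "n_mprs": len(result.reconstructions),
        "mprs_truncated": result.truncated,
        "universe_size": len(result.universe),
        "per_mpr_counts": per_mpr_counts,
    }
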