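# cophymap

Greedy, near-linear-time cophylogeny mapping. Given a *tanglegram* — a
rooted bifurcating host tree, a parasite tree, and a leaf association table
— `cophymap` reconstructs a time-consistent event history (codivergence,
duplication, host switch, loss) for the parasite inside the host.

The core algorithm fixes an integer *node ordering* on the host's internal
nodes, consumes host cherries deepest-first, and classifies local
host/parasite cherry configurations against an eight-pattern table (four
base patterns plus four two-event hybrid bundles). Because cherries are
processed in strictly decreasing depth order, every recorded host switch
lands on an edge that coexists in time with its takeoff edge, so the output
is biologically feasible by construction. A post-processing pass (*switch
relocation*) pushes takeoff/landing edges toward the leaves to remove
over-counted losses, using level-ancestor queries. A genetic algorithm
searches the exponential space of node orderings using the collapse cost as
fitness.

Also included:

- `page_reconcile` — classical LCA reconciliation (no switches allowed),
- `edge_only_map` — duplication/switch-only mapping confined to leaf-adjacent
  edges (an upper-bound baseline),
- `exact_dp` — an exact fixed-ordering dynamic program, size-guarded, used
  as the correctness oracle in the test suite,
- `simulate` — a Yule-process cophylogeny generator for synthetic data.

Costs default to the scheme (codivergence, duplication, switch, loss) =
(0, 1, 2, 1); any non-negative weights can be supplied.

## Library quick start

```python
from cophymap import (
    read_tanglegram, tree_collapse, right_push, run_ga, GAConfig,
)

tg = read_tanglegram(
    open("host.nwk").read(), open("parasite.nwk").read(),
    open("links.tsv").read(),          # parasite<TAB>host rows
)
mapping = right_push(tree_collapse(tg))      # default ordering
print(mapping.counts(), mapping.cost())

best, cost, history = run_ga(tg, GAConfig(rng_seed=1))   # search orderings
```

## Command line

```sh
cophymap simulate --leaves 16 --seed 1 --prefix demo
cophymap collapse demo.host.nwk demo.parasite.nwk demo.links.tsv --out report.json
cophymap search   demo.host.nwk demo.parasite.nwk demo.links.tsv --pop 100 --gens 100 --seed 1
cophymap baseline demo.host.nwk demo.parasite.nwk demo.links.tsv --method page
cophymap audit    report.json
```

Subcommands: `collapse`, `search`, `baseline` (`page` / `edge-only` /
`exact-dp`), `simulate`, `audit`. Useful flags: `--scheme c,d,s,l`,
`--ordering FILE` (TSV `clade<TAB>depth`, clades written as sorted leaf
labels joined with `|`), `--no-right-push`, `--no-hybrids`,
`--disable-pattern KIND`, `--seed N`, `--out FILE`. Exit codes: 0 ok,
1 audit failure, 2 input error, 3 size-guard refusal.

## Layout

- `src/cophymap/model.py` — trees, tanglegrams, orderings, events, the
  time-consistency audit, and the canonical loss derivation
- `src/cophymap/formats.py` — Newick / TSV / JSON report I/O
- `src/cophymap/collapse.py` — pattern detection and the collapse loop
- `src/cophymap/rightpush.py` — level-ancestor index and switch relocation
- `src/cophymap/ga.py` — genetic algorithm over node orderings
- `src/cophymap/baselines.py` — Page-style, edge-only, and exact-DP oracles
- `src/cophymap/simulate.py` — Yule cophylogeny generator
- `src/cophymap/cli.py` — command-line interface
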