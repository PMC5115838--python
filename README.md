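# sibnet

Singleton attractors, pre-images and basins of attraction for
**strong-inhibition Boolean networks** — the dominant-inhibition limit
of threshold Boolean models of gene regulation.

## What problem this solves

Gene regulatory networks are commonly modelled as Boolean networks: each
gene is on (1) or off (0) and all genes update synchronously from the
signed wiring diagram. The stable outcomes of such a system are its
attractors; the *singleton* attractors (fixed points, states with
S(t+1) = S(t)) correspond to stable cellular phenotypes such as
differentiated states. Finding them by enumerating all 2^N states is
hopeless beyond small N, and the related predecessor problem — which
states map onto a given state in one step — is NP-hard in general.

In the strong-inhibition model a single active inhibitor switches its
target off regardless of how many activators are on:

    S_i(t+1) = ( OR_{j≠i} S_j g_ij  OR  S_i ∧ ¬r_ii  OR  ¬S_i ∧ g_ii )
               AND NOT ( OR_{j≠i} S_j r_ij )

where g_ij / r_ij indicate an activating / inhibiting edge from gene j
to gene i. This structure makes the fixed-point condition highly
local: `sibnet` exploits it with a branch-and-propagate search —
constraint-propagation rules pin down node states entailed by a partial
assignment, a heuristic branches on the node with the most inhibitory
connections, and contradictions prune whole subtrees. The same skeleton
with a reversed rule set enumerates all pre-images of any target state,
and iterating pre-images reconstructs the basin of attraction of a
fixed point layer by layer (layer d = states exactly d steps from the
attractor). Exhaustive 2^N oracles are included for validation, and a
random-ensemble harness characterises how the attractor count NS — and
with it the search effort — depends on network size N, average degree
⟨k⟩ and inhibitory edge fraction r.

Audience: systems-biology researchers analysing signed regulatory
networks (logical modelling, attractor/basin analysis) and anyone
studying the combinatorics of threshold Boolean dynamics.

## Worked example

The bundled fixture is the budding-yeast cell-cycle network (11 genes,
34 signed edges). Its seven fixed points, the pre-images of the main
one, and its basin:

```pycon
>>> import sibnet as sb
>>> net = sb.budding_yeast()
>>> attractors, stats = sb.enumerate_singleton_attractors(net)
>>> sorted(attractors)
['00000000000', '00000000100', '00001000000', '00001000100',
 '00110000000', '01000000100', '01001000100']
>>> stats.nodes_expanded, stats.contradictions
(9, 3)
```

Bitstrings list node 1 (Cln3) leftmost; `00001000100` is the biological
G1 state, with Cdh1 (node 5) and Sic1 (node 9) on. Nine branchings and
three pruned contradictions suffice instead of scanning 2^11 = 2048
states. Its one-step pre-images and basin:

```pycon
>>> sorted(sb.enumerate_preimages(net, "00001000100")[0])
['00001000100', '00001100000', '00001100100']
>>> basin = sb.compute_basin(net, "00001000100")
>>> basin.size, basin.depth
(1875, 11)
```

So 1875 of the 2048 states flow into the G1 fixed point, the farthest
of them 11 steps away. The same from the command line:

```
$ sibnet attractors yeast.tsv --stats
00000000000
...
$ sibnet preimages yeast.tsv --target 00001000100
$ sibnet basin yeast.tsv --attractor 00001000100 --format json
$ sibnet random-net -N 50 -k 3 -r 0.4 --seed 1 --output rand.tsv
$ sibnet ensemble -N 14 -k 3 -r 0.4 -M 200 --seed 1 --out records.csv
```

Network files are plain-text signed adjacency matrices (`a[i][j]` =
effect of column node j on row node i) or three-column edge lists
`source  target  sign`; see `docs/methods.md` for the model, the rule
sets, and all design choices.

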