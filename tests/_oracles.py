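"""Independent brute-force reference implementations used only by tests.

Everything here is deliberately scalar/loop-based and written from the
mathematical definitions, so it shares no code path with the vectorized
package implementations it checks.
"""

import math

import numpy as np


def cutoff_scalar(r, rc):
    if r > rc:
        return 0.0
    return 0.5 * (math.cos(math.pi * r / rc) + 1.0)


def aev_brute_force(lig_xyz, prot_xyz, prot_types, n_types, rs_values, eta_values, rc):
    """Double loop over atoms and (t, Rs, eta) shells."""
    L, K = len(rs_values), len(eta_values)
    out = np.zeros(n_types * L * K)
    for j in range(len(prot_xyz)):
        t = prot_types[j]
        if t < 0:
            continue
        r = math.dist(lig_xyz, prot_xyz[j])
        for l, rs in enumerate(rs_values):
            for k, eta in enumerate(eta_values):
                idx = t * L * K + l * K + k
                out[idx] += math.exp(-eta * (r - rs) ** 2) * cutoff_scalar(r, rc)
    return out


def attention_scalar(x, edges, edge_feat, Ws, Wt, We, b, slope=0.2):
    """Attention coefficients per directed edge (list aligned with edges).

    ``edges`` are (src, dst) pairs including self loops; softmax over all
    edges sharing a dst.
    """
    scores = []
    for (s, d), e in zip(edges, edge_feat):
        z = Ws.T @ x[d] + Wt.T @ x[s] + We.T @ np.asarray(e)
        z = np.where(z > 0, z, slope * z)
        scores.append(float(b[:, 0] @ z))
    coeffs = []
    for k, (s, d) in enumerate(edges):
        denom = sum(
            math.exp(scores[m]) for m, (_, d2) in enumerate(edges) if d2 == d
        )
        coeffs.append(math.exp(scores[k]) / denom)
    return coeffs


def gat_layer_scalar(x, edges, edge_feat, heads, slope=0.2, activation="relu"):
    """One GATv2 layer, per-node loops; heads = [(Ws, Wt, We, b), ...]."""
    n = len(x)
    outs = []
    for Ws, Wt, We, b in heads:
        a = attention_scalar(x, edges, edge_feat, Ws, Wt, We, b, slope)
        h = np.zeros((n, Wt.shape[1]))
        for k, (s, d) in enumerate(edges):
            h[d] += a[k] * (Wt.T @ x[s])
        outs.append(h)
    h = np.concatenate(outs, axis=1)
    if activation == "relu":
        h = np.maximum(h, 0.0)
    return h


def pool_scalar(x):
    n, d = x.shape
    mx = [max(x[i][j] for i in range(n)) for j in range(d)]
    mn = [sum(x[i][j] for i in range(n)) / n for j in range(d)]
    return np.array(mx + mn)


def pcc_two_pass(x, y):
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((x[i] - mx) * (y[i] - my) for i in range(n))
    den = math.sqrt(
        sum((x[i] - mx) ** 2 for i in range(n))
        * sum((y[i] - my) ** 2 for i in range(n))
    )
    return num / den


def kendall_tau_enumerate(x, y):
    n = len(x)
    nc = nd = 0
    for i in range(n):
        for j in range(i + 1, n):
            s = (x[j] - x[i]) * (y[j] - y[i])
            if s > 0:
                nc += 1
            elif s < 0:
                nd += 1
    return (nc - nd) / (0.5 * n * (n - 1))


def threshold_components(distances, threshold):
    """Connected components of the graph joining pairs with d < threshold."""
    import networkx as nx

    n = distances.shape[0]
    g = nx.Graph()
    g.add_nodes_from(range(n))
    for i in range(n):
        for j in range(i + 1, n):
            if distances[i, j] < threshold:
                g.add_edge(i, j)
    labels = np.empty(n, dtype=int)
    comps = sorted(nx.connected_components(g), key=min)
    for lab, comp in enumerate(comps):
        for i in comp:
            labels[i] = lab
    return labels


def canon_labels(labels):
    """Relabel cluster ids by first occurrence so labelings compare equal."""
    remap = {}
    return np.array([remap.setdefault(int(l), len(remap)) for l in labels])
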