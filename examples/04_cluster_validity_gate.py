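"""The validity gate: what counts as evidence for enterotype-like clusters.

Scores two partitions in their embedding spaces — planted well-separated
clusters versus an arbitrary cut through a continuous gradient — with DBCV,
prediction strength, silhouette, Davies-Bouldin, entropy and the 5% balance
rule, exactly as the full framework does.
"""

from enteromap import (fit_pca, generate_clustered, generate_gradient, pam,
                       sweep_hyperparams)
from enteromap.validity import score_partition


def show(name, m):
    print(f"{name}:")
    print(f"  dbcv={m.dbcv:+.3f}  ps={m.prediction_strength:.3f}  "
          f"silhouette={m.silhouette:.3f}  davies_bouldin={m.davies_bouldin:.3f}")
    print(f"  entropy={m.entropy:.3f}  min_mass={m.min_mass:.3f}")
    print(f"  density pair {'PASS' if m.pass_density_pair else 'fail'}, "
          f"convex pair {'PASS' if m.pass_convex_pair else 'fail'}, "
          f"balanced {'PASS' if m.balanced else 'fail'} "
          f"=> pass_all={m.pass_all}")


def embed_2d(abundances, seed=0):
    _, scores = fit_pca(abundances)
    d_target = min(2, scores.shape[1])  # the gradient needs a single PC
    emb = sweep_hyperparams(scores, "isomap", [{"n_neighbors": 30}], d_target,
                            seed=seed, X_score=abundances)
    return emb.coords


# planted structure: 3 separated logistic-normal clusters
ds = generate_clustered(n=600, p=40, k=3, separation=5.0, spread=1.0, seed=0)
coords = embed_2d(ds.abundances)
part = pam(coords, k=3, seed=0)
m = score_partition(coords, part,
                    ps_clusterer=lambda X, s: pam(X, k=3, seed=s), seed=0)
show("planted 3 clusters, PAM k=3 in the embedding", m)

# continuous gradient: any k=2 cut is arbitrary
grad = generate_gradient(n=600, p=40, seed=0)
gcoords = embed_2d(grad.abundances)
gpart = pam(gcoords, k=2, seed=0)
gm = score_partition(gcoords, gpart,
                     ps_clusterer=lambda X, s: pam(X, k=2, seed=s), seed=0)
show("continuous gradient, PAM k=2 in the embedding", gm)
# A stable, balanced cut (high PS) through a continuum still fails DBCV:
# there is no density gap along the Bacteroides/Prevotella-like trade-off.
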