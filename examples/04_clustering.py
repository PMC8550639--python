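"""Model-based clustering with unknown numbers of clusters and states.

Two well-separated single-state populations; the clustering sampler infers
both the number of mixture components M, the number of occupied clusters
M*, and each component's state count, then assigns subjects to their modal
cluster.
"""

import numpy as np

from cthmm import (BetaCoefPrior, ClusterMoveConfig, GLMFamily, MoveConfig,
                   PriorSpec, Subject, cluster_sweep, init_cluster_state,
                   pack_subjects)

rng = np.random.default_rng(3)
ys = [-6.0] * 25 + [6.0] * 25
subjects = [Subject(np.array([0.0, 1.0, 2.0]),
                    y + rng.normal(0, 1.0, 3), np.ones((3, 1)),
                    subject_id=i + 1)
            for i, y in enumerate(ys)]
packed = pack_subjects(subjects)

prior = PriorSpec(beta_prior=BetaCoefPrior("normal", 0.0, 25.0))
state = init_cluster_state(packed, GLMFamily("normal", 1.0), prior, rng)
mstars, members = [], []
for i in range(400):
    state, rec = cluster_sweep(state, packed, prior,
                               ClusterMoveConfig(Mmax=6), MoveConfig(Kmax=1),
                               rng)
    if i >= 150:
        mstars.append(rec["M_star"])
        members.append(state.memberships.copy())

modal_mstar = int(np.bincount(mstars).argmax())
print(f"posterior mode of the number of occupied clusters: {modal_mstar} "
      "(the data were generated from 2 populations)")
members = np.stack(members)
same = np.mean([(members[i, :25] == members[i, 0]).all()
                and (members[i, 25:] == members[i, 25]).all()
                and members[i, 0] != members[i, 25]
                for i in range(members.shape[0])])
print(f"fraction of sweeps that split the subjects exactly along the true "
      f"populations: {same:.3f}")
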