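"""Numba core of the trajectory-conditional structured coalescent.

Lineages carry ancestral-material segments and an allelic background at the
focal site (1 = derived, 0 = ancestral).  Backward in time, pair coalescence
within background ``b`` occurs at rate ``C(k_b,2) / (2 N(t) x_b(t))`` with
``x_derived = x(t)`` from the trajectory; recombination occurs per lineage at
the genetic-map length of the hull of (material ∪ focal site), and a
breakpoint separating material from the focal site redraws that material's
background (derived with probability ``x(t)``).  When the trajectory absorbs,
remaining derived lineages join the ancestral background (the focal mutation
event) and a plain coalescent-with-recombination runs to the local MRCAs.

Neutral mutations are attached directly to segments: every segment carries the
bitmask of sampled haplotypes descending from it, and when a segment dies
(merge) it emits Poisson(mu * length * lifetime) mutations, each inheriting
the segment's descendant set.  Segments whose descendant set reaches all
samples are local MRCAs and are dropped (their mutations would be fixed in the
sample).  No explicit tree is ever built.

Status codes: 0 ok, 1 segment-pool overflow, 2 lineage-pool overflow,
3 mutation-buffer overflow, 4 event-cap exceeded, 5 internal inconsistency.
"""

import numpy as np
from numba import njit

MASKW = 4  # uint64 words per descendant bitmask -> up to 256 haplotypes


@njit(cache=True)
def _cum(pos, map_bp, map_M):
    j = np.searchsorted(map_bp, pos)
    if j <= 0:
        return map_M[0]
    if j >= map_bp.shape[0]:
        return map_M[map_M.shape[0] - 1]
    lo = map_bp[j - 1]
    hi = map_bp[j]
    if hi == lo:
        return map_M[j]
    f = (pos - lo) / (hi - lo)
    return map_M[j - 1] + f * (map_M[j] - map_M[j - 1])


@njit(cache=True)
def _inv_cum(g, map_bp, map_M):
    j = np.searchsorted(map_M, g)
    if j <= 0:
        return map_bp[0]
    if j >= map_M.shape[0]:
        return map_bp[map_bp.shape[0] - 1]
    lo = map_M[j - 1]
    hi = map_M[j]
    if hi == lo:
        return map_bp[j]
    f = (g - lo) / (hi - lo)
    return map_bp[j - 1] + f * (map_bp[j] - map_bp[j - 1])


@njit(cache=True)
def sim_kernel(seed, traj, dt, ep_starts, ep_N, n_der, n_anc, L, focal,
               map_bp, map_M, mu,
               seg_l, seg_r, seg_mask, seg_birth, seg_next,
               mut_pos, mut_mask, max_events):
    np.random.seed(seed)
    n = n_der + n_anc
    max_seg = seg_l.shape[0]
    max_lin = max_seg
    max_mut = mut_pos.shape[0]
    n_ep = ep_starts.shape[0]
    n_traj = traj.shape[0]

    full = np.zeros(MASKW, dtype=np.uint64)
    for i in range(n):
        full[i // 64] |= np.uint64(1) << np.uint64(i % 64)

    # pools ------------------------------------------------------------
    seg_free = np.empty(max_seg, dtype=np.int64)
    for i in range(max_seg):
        seg_free[i] = max_seg - 1 - i

    lin_head = np.full(max_lin, -1, dtype=np.int64)
    lin_bg = np.zeros(max_lin, dtype=np.int64)
    lin_rec = np.zeros(max_lin, dtype=np.float64)
    lin_ga = np.zeros(max_lin, dtype=np.float64)
    lin_gb = np.zeros(max_lin, dtype=np.float64)
    lin_slot = np.zeros(max_lin, dtype=np.int64)
    lin_free = np.empty(max_lin, dtype=np.int64)
    for i in range(max_lin):
        lin_free[i] = max_lin - 1 - i

    cls = np.empty((2, max_lin), dtype=np.int64)
    cls_n = np.zeros(2, dtype=np.int64)

    # st: 0 seg_free_top, 1 lin_free_top, 2 n_mut, 3 n_active_seg,
    #     4 status, 5 events, 6 two_class flag
    st = np.zeros(8, dtype=np.int64)
    st[0] = max_seg
    st[1] = max_lin
    st[6] = 1
    tot = np.zeros(1, dtype=np.float64)  # total recombination rate (Morgans/gen)

    def seg_alloc():
        if st[0] <= 0:
            st[4] = 1
            return 0
        st[0] -= 1
        return seg_free[st[0]]

    def seg_release(s):
        seg_free[st[0]] = s
        st[0] += 1

    def flush(s, t):
        lam = mu * (seg_r[s] - seg_l[s]) * (t - seg_birth[s])
        if lam <= 0.0:
            return
        k = np.random.poisson(lam)
        for _ in range(k):
            m = st[2]
            if m >= max_mut:
                st[4] = 3
                return
            mut_pos[m] = seg_l[s] + np.random.random() * (seg_r[s] - seg_l[s])
            for w in range(MASKW):
                mut_mask[m, w] = seg_mask[s, w]
            st[2] = m + 1

    def kill_lineage(lin):
        bg = lin_bg[lin]
        slot = lin_slot[lin]
        last = cls_n[bg] - 1
        moved = cls[bg, last]
        cls[bg, slot] = moved
        lin_slot[moved] = slot
        cls_n[bg] = last
        tot[0] -= lin_rec[lin]
        lin_free[st[1]] = lin
        st[1] += 1

    def new_lineage(head, bg):
        if st[1] <= 0:
            st[4] = 2
            return
        st[1] -= 1
        lin = lin_free[st[1]]
        lin_head[lin] = head
        lin_bg[lin] = bg
        mn = 1.0e300
        mx = -1.0e300
        s = head
        while s != -1:
            if seg_l[s] < mn:
                mn = seg_l[s]
            if seg_r[s] > mx:
                mx = seg_r[s]
            s = seg_next[s]
        if st[6] == 1:
            if focal < mn:
                mn = focal
            if focal > mx:
                mx = focal
        ga = _cum(mn, map_bp, map_M)
        gb = _cum(mx, map_bp, map_M)
        lin_ga[lin] = ga
        lin_gb[lin] = gb
        lin_rec[lin] = gb - ga
        tot[0] += lin_rec[lin]
        slot = cls_n[bg]
        cls[bg, slot] = lin
        lin_slot[lin] = slot
        cls_n[bg] = slot + 1

    def emit(l, r, src_a, src_b, tail, t):
        # append piece [l,r) with mask(src_a) | mask(src_b) (src_b may be -1);
        # returns new tail (or tail unchanged).  Full-mask pieces are local
        # MRCAs and are dropped.
        if r <= l:
            return tail
        is_full = True
        for w in range(MASKW):
            mw = seg_mask[src_a, w]
            if src_b != -1:
                mw |= seg_mask[src_b, w]
            if mw != full[w]:
                is_full = False
        if is_full:
            return tail
        s = seg_alloc()
        if st[4] != 0:
            return tail
        seg_l[s] = l
        seg_r[s] = r
        for w in range(MASKW):
            mw = seg_mask[src_a, w]
            if src_b != -1:
                mw |= seg_mask[src_b, w]
            seg_mask[s, w] = mw
        seg_birth[s] = t
        seg_next[s] = -1
        if tail != -1:
            seg_next[tail] = s
        st[3] += 1
        return s

    def merge_chains(ha, hb, t):
        # flush parents (their masks applied over their full life)
        a = ha
        while a != -1:
            flush(a, t)
            st[3] -= 1
            a = seg_next[a]
        b = hb
        while b != -1:
            flush(b, t)
            st[3] -= 1
            b = seg_next[b]
        out_head = -1
        out_tail = -1
        a = ha
        b = hb
        la = seg_l[a] if a != -1 else 0.0
        lb = seg_l[b] if b != -1 else 0.0
        while a != -1 and b != -1:
            ra = seg_r[a]
            rb = seg_r[b]
            if ra <= lb:
                out_tail = emit(la, ra, a, -1, out_tail, t)
                if out_head == -1:
                    out_head = out_tail
                a = seg_next[a]
                if a != -1:
                    la = seg_l[a]
            elif rb <= la:
                out_tail = emit(lb, rb, b, -1, out_tail, t)
                if out_head == -1:
                    out_head = out_tail
                b = seg_next[b]
                if b != -1:
                    lb = seg_l[b]
            elif la < lb:
                out_tail = emit(la, lb, a, -1, out_tail, t)
                if out_head == -1:
                    out_head = out_tail
                la = lb
            elif lb < la:
                out_tail = emit(lb, la, b, -1, out_tail, t)
                if out_head == -1:
                    out_head = out_tail
                lb = la
            else:
                e = ra if ra < rb else rb
                out_tail = emit(la, e, a, b, out_tail, t)
                if out_head == -1:
                    out_head = out_tail
                la = e
                lb = e
                if e >= ra:
                    a = seg_next[a]
                    if a != -1:
                        la = seg_l[a]
                if e >= rb:
                    b = seg_next[b]
                    if b != -1:
                        lb = seg_l[b]
        while a != -1:
            out_tail = emit(la, seg_r[a], a, -1, out_tail, t)
            if out_head == -1:
                out_head = out_tail
            a = seg_next[a]
            if a != -1:
                la = seg_l[a]
        while b != -1:
            out_tail = emit(lb, seg_r[b], b, -1, out_tail, t)
            if out_head == -1:
                out_head = out_tail
            b = seg_next[b]
            if b != -1:
                lb = seg_l[b]
        # release parent segments
        a = ha
        while a != -1:
            nxt = seg_next[a]
            seg_release(a)
            a = nxt
        b = hb
        while b != -1:
            nxt = seg_next[b]
            seg_release(b)
            b = nxt
        return out_head

    def coalesce(bg, t):
        k = cls_n[bg]
        i = np.random.randint(0, k)
        j = np.random.randint(0, k - 1)
        if j >= i:
            j += 1
        la_ = cls[bg, i]
        lb_ = cls[bg, j]
        ch = merge_chains(lin_head[la_], lin_head[lb_], t)
        kill_lineage(la_)
        kill_lineage(lb_)
        if ch != -1:
            new_lineage(ch, bg)
        st[5] += 1

    def split_chain(head, bp):
        # -> (left_head, right_head); material strictly left / right of bp
        left_head = -1
        left_tail = -1
        right_head = -1
        cur = head
        while cur != -1:
            nxt = seg_next[cur]
            if seg_r[cur] <= bp:
                if left_tail != -1:
                    seg_next[left_tail] = cur
                else:
                    left_head = cur
                left_tail = cur
                seg_next[cur] = -1
                cur = nxt
            elif seg_l[cur] >= bp:
                right_head = cur
                break
            else:
                s2 = seg_alloc()
                if st[4] != 0:
                    return left_head, right_head
                seg_l[s2] = bp
                seg_r[s2] = seg_r[cur]
                for w in range(MASKW):
                    seg_mask[s2, w] = seg_mask[cur, w]
                seg_birth[s2] = seg_birth[cur]
                seg_next[s2] = nxt
                st[3] += 1
                seg_r[cur] = bp
                if left_tail != -1:
                    seg_next[left_tail] = cur
                else:
                    left_head = cur
                seg_next[cur] = -1
                right_head = s2
                break
        return left_head, right_head

    def recombine(t, x):
        u = np.random.random() * tot[0]
        acc = 0.0
        lin = -1
        for bgi in range(2):
            for ii in range(cls_n[bgi]):
                cand = cls[bgi, ii]
                acc += lin_rec[cand]
                if acc >= u:
                    lin = cand
                    break
            if lin != -1:
                break
        if lin == -1:
            # numerical slack: pick any positive-rate lineage
            for bgi in range(2):
                for ii in range(cls_n[bgi]):
                    cand = cls[bgi, ii]
                    if lin_rec[cand] > 0.0:
                        lin = cand
            if lin == -1:
                return
        g = lin_ga[lin] + np.random.random() * (lin_gb[lin] - lin_ga[lin])
        bp = _inv_cum(g, map_bp, map_M)
        lh, rh = split_chain(lin_head[lin], bp)
        if st[4] != 0:
            return
        old_bg = lin_bg[lin]
        kill_lineage(lin)
        if st[6] == 1:
            nb = 1 if np.random.random() < x else 0
            if focal < bp:  # focal side = left
                if lh != -1:
                    new_lineage(lh, old_bg)
                if rh != -1:
                    new_lineage(rh, nb)
            else:
                if rh != -1:
                    new_lineage(rh, old_bg)
                if lh != -1:
                    new_lineage(lh, nb)
        else:
            if lh != -1:
                new_lineage(lh, 0)
            if rh != -1:
                new_lineage(rh, 0)
        st[5] += 1

    # ---- initial sample ------------------------------------------------
    for i in range(n):
        s = seg_alloc()
        seg_l[s] = 0.0
        seg_r[s] = L
        for w in range(MASKW):
            seg_mask[s, w] = np.uint64(0)
        seg_mask[s, i // 64] = np.uint64(1) << np.uint64(i % 64)
        seg_birth[s] = 0.0
        seg_next[s] = -1
        st[3] += 1
        new_lineage(s, 1 if i < n_der else 0)

    # ---- sweep phase: follow the trajectory ----------------------------
    ep = 0
    for i in range(n_traj):
        if st[3] == 0 or st[4] != 0:
            break
        x = traj[i]
        t_base = i * dt
        while ep + 1 < n_ep and ep_starts[ep + 1] <= t_base:
            ep += 1
        N = ep_N[ep]
        # frequency cannot support more lineages than copies
        while cls_n[1] > 1 and 2.0 * N * x < cls_n[1]:
            coalesce(1, t_base)
            if st[4] != 0:
                break
        while cls_n[0] > 1 and 2.0 * N * (1.0 - x) < cls_n[0]:
            coalesce(0, t_base)
            if st[4] != 0:
                break
        if st[3] == 0 or st[4] != 0:
            break
        tau = 0.0
        while True:
            kd = cls_n[1]
            ka = cls_n[0]
            cr_d = 0.0
            if kd >= 2 and x > 0.0:
                cr_d = kd * (kd - 1) * 0.5 / (2.0 * N * x)
            cr_a = 0.0
            if ka >= 2 and x < 1.0:
                cr_a = ka * (ka - 1) * 0.5 / (2.0 * N * (1.0 - x))
            R = cr_d + cr_a + tot[0]
            if R <= 0.0:
                break
            w = np.random.exponential(1.0 / R)
            if tau + w >= dt:
                break
            tau += w
            u = np.random.random() * R
            if u < cr_d:
                coalesce(1, t_base + tau)
            elif u < cr_d + cr_a:
                coalesce(0, t_base + tau)
            else:
                recombine(t_base + tau, x)
            if st[3] == 0 or st[4] != 0:
                break
            if st[5] > max_events:
                st[4] = 4
                break
        if st[4] != 0:
            break

    # ---- absorption: focal mutation event, single background -----------
    t_now = n_traj * dt
    if st[3] > 0 and st[4] == 0:
        st[6] = 0
        # re-register every lineage with a material-only hull
        heads = np.empty(max_lin, dtype=np.int64)
        nh = 0
        for bgi in range(2):
            while cls_n[bgi] > 0:
                l_ = cls[bgi, 0]
                heads[nh] = lin_head[l_]
                nh += 1
                kill_lineage(l_)
        for ii in range(nh):
            new_lineage(heads[ii], 0)

        while st[3] > 0 and st[4] == 0:
            while ep + 1 < n_ep and ep_starts[ep + 1] <= t_now:
                ep += 1
            N = ep_N[ep]
            k = cls_n[0]
            cr = 0.0
            if k >= 2:
                cr = k * (k - 1) * 0.5 / (2.0 * N)
            R = cr + tot[0]
            if R <= 0.0:
                st[4] = 5
                break
            w = np.random.exponential(1.0 / R)
            if ep + 1 < n_ep and t_now + w >= ep_starts[ep + 1]:
                t_now = ep_starts[ep + 1]
                continue
            t_now += w
            u = np.random.random() * R
            if u < cr:
                coalesce(0, t_now)
            else:
                recombine(t_now, 0.0)
            if st[5] > max_events:
                st[4] = 4

    return st[2], st[4], st[5], t_now
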