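"""Synthetic chat-corpus generator.

Emulates the statistical structure of first consultations at a 24/7
chat-counseling service for young people: over-dispersed per-speaker
message counts, a heavy-tailed total word count, a ~43% six-month
recontact prevalence driven by word-level latent factors (age, gender,
self-harm/suicide topics, work topics, counselor redirection, nighttime
contact), counselor mirroring of chatter topic words, and a recontact
delay distribution with most mass inside the first week.

Every downstream stage of the pipeline (sessionization, anonymization,
vectorization, modeling, explainability) is testable against this
generator's ground truth without any real chat data.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "CountDist",
    "DelayMixture",
    "SynthConfig",
    "GroundTruth",
    "calibrate_intercept",
    "generate_corpus",
    "default_topic_lexicons",
]

SECONDS_PER_DAY = 86400.0


@dataclass(frozen=True)
class CountDist:
    """Mean/SD specification of an over-dispersed count distribution.

    Realized as a negative binomial (SD must exceed what a Poisson with the
    same mean would give); ``cap`` is an optional hard upper truncation.
    """

    mean: float
    sd: float
    cap: int | None = None

    def nbinom(self, mean: float | None = None) -> stats.rv_discrete:
        """Frozen scipy negative binomial with this SD and the given mean."""
        m = self.mean if mean is None else mean
        var = self.sd**2
        if var <= m:
            raise ValueError(f"count dist needs sd^2 > mean, got {self}")
        r = m * m / (var - m)
        p = r / (r + m)
        return stats.nbinom(r, p)


@dataclass(frozen=True)
class DelayMixture:
    """Recontact delay (days): early uniform week + truncated exponential tail."""

    p_week: float = 0.55
    early_lo: float = 0.30  # > 6 h so the recontact is a new consultation
    early_hi: float = 7.0
    tail_scale: float = 35.0
    max_days: float = 188.0

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        early = rng.random(size) < self.p_week
        out = np.empty(size)
        out[early] = rng.uniform(self.early_lo, self.early_hi, early.sum())
        n_tail = (~early).sum()
        # inverse-CDF of Exp(tail_scale) truncated to (early_hi, max_days]
        u = rng.random(n_tail)
        c = 1.0 - np.exp(-(self.max_days - self.early_hi) / self.tail_scale)
        out[~early] = self.early_hi - self.tail_scale * np.log1p(-u * c)
        return out


def default_topic_lexicons() -> dict[str, list[str]]:
    """Stem lexicons per topic (synthetic German-like stems, pre-stemmed)."""
    return {
        "self_harm": ["verletz", "ritz", "schneid", "narb", "wund"],
        "suicide": ["suizid", "selbstmord", "sterb", "umbring", "gedank-dunkel"],
        "work": ["arbeit", "job", "chef", "ausbild", "kolleg"],
        "redirection": [
            "professionell", "internetseelsorg", "rat", "therapeut",
            "beratungsstell", "weiterleit",
        ],
        "time_of_day": ["nacht", "tagsub", "abend", "morg", "schlaf", "spat"],
        "emotion_adjectives": [
            "allein", "schwach", "falsch", "traurig", "leer", "wertlos",
            "verzweifelt",
        ],
        "numbers": [str(a) for a in range(12, 25)],
        "background": _default_background(),
    }


def _default_background() -> list[str]:
    return [
        "ich", "du", "das", "nicht", "und", "ist", "mir", "mich", "so",
        "aber", "wie", "was", "dann", "auch", "mal", "wenn", "mit", "fur",
        "schon", "mehr", "immer", "heut", "mach", "gut", "denk", "fuhl",
        "red", "sag", "weiss", "kann", "muss", "will", "hab", "bin",
        "geht", "gibt", "leb", "mensch", "freund", "schul", "eltern",
        "mutter", "vater", "bruder", "schwest", "angst", "problem",
        "hilf", "dank", "situation", "gefuhl", "tag", "woch", "lehrer",
        "klass", "handy", "zuhaus", "wohn", "stadt", "haus", "weg",
        "lang", "kurz", "gross", "klein", "neu", "alt", "gern", "oft",
        "viel", "wenig", "ander", "erst", "letzt", "frag", "antwort",
        "erzahl", "hor", "versteh", "glaub", "hoff", "wunsch", "brauch",
        "versuch", "schaff", "streit", "ruh", "laut", "leis", "stark",
        "mud", "wach", "ess", "trink", "geh", "komm", "bleib", "fahr",
        "lern", "spiel", "musik", "sport", "buch", "film", "serie",
        "insta", "chat", "nachricht", "schreib", "les", "warte", "treff",
    ]


def _default_age_pmf() -> np.ndarray:
    """Discrete ages 12..24, mean 17 (binomial(12, 5/12) shifted)."""
    return stats.binom(12, 5.0 / 12.0).pmf(np.arange(13))


def _default_hour_pmf() -> np.ndarray:
    """Clock-hour distribution with an evening peak and a thin early morning."""
    w = np.array(
        [3.0, 2.0, 1.5, 1.0, 1.0, 1.0, 1.5, 2.0, 3.0, 4.0, 5.0, 5.0,
         5.0, 5.5, 6.0, 6.5, 7.0, 8.0, 9.0, 10.0, 11.0, 12.0, 9.0, 5.0]
    )
    return w / w.sum()


@dataclass
class SynthConfig:
    """Full parameterization of the synthetic corpus generator."""

    n_chatters: int = 1000
    seed: int = 0
    target_prevalence: float = 0.431
    chatter_msg_dist: CountDist = field(default_factory=lambda: CountDist(25.4, 20.8))
    counselor_msg_dist: CountDist = field(default_factory=lambda: CountDist(17.7, 12.1))
    total_words_dist: CountDist = field(
        default_factory=lambda: CountDist(456.4, 283.9, cap=3340)
    )
    age_pmf: np.ndarray = field(default_factory=_default_age_pmf)  # ages 12..24
    age_lo: int = 12
    p_female: float = 0.65
    topic_lexicons: dict[str, list[str]] = field(default_factory=default_topic_lexicons)
    topic_priors: dict[str, float] = field(
        default_factory=lambda: {
            "self_harm": 0.25,
            "suicide": 0.15,
            "work": 0.20,
            "redirection": 0.30,
            "time_of_day_base": 0.10,  # daytime chance; always active at night
            "emotion_adjectives": 0.50,
        }
    )
    effect_log_odds: dict[str, float] = field(
        default_factory=lambda: {
            "young": 0.9,
            "female": 0.5,
            "male": -0.5,
            "self_harm": 0.8,
            "suicide": 0.9,
            "night": 0.5,
            "work": -0.8,
            "redirection": -0.7,
        }
    )
    mirror_prob: float = 2.0 / 3.0
    recontact_delay: DelayMixture = field(default_factory=DelayMixture)
    start_time_pmf: np.ndarray = field(default_factory=_default_hour_pmf)
    night_hours: tuple[int, ...] = (22, 23, 0, 1, 2, 3, 4, 5)
    young_age_max: int = 14
    p_mention_age: float = 0.8
    p_mention_gender: float = 0.65
    female_stems: tuple[str, ...] = ("weiblich", "madch")
    male_stems: tuple[str, ...] = ("mannlich", "kerl")
    calendar_start: str = "2021-10-01"
    calendar_end: str = "2022-12-31"
    p_nonqualifying: float = 0.0
    min_counselor: int = 3
    min_total: int = 10
    topic_token_rate: float = 0.04  # forced topic tokens per word of channel text
    background_zipf: float = 1.1

    def validate(self) -> None:
        probs = [
            self.target_prevalence, self.p_female, self.mirror_prob,
            self.p_mention_age, self.p_mention_gender, self.p_nonqualifying,
            *self.topic_priors.values(),
        ]
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise ValueError("all probabilities must lie in [0, 1]")
        for d in (self.chatter_msg_dist, self.counselor_msg_dist, self.total_words_dist):
            if d.mean <= 0 or d.sd <= 0:
                raise ValueError("count distributions need positive mean and sd")
        lexs = list(self.topic_lexicons.values())
        seen: set[str] = set()
        for lex in lexs:
            s = set(lex)
            if s & seen:
                raise ValueError(f"topic lexicons not pairwise disjoint: {s & seen}")
            seen |= s
        if self.n_chatters <= 0:
            raise ValueError("n_chatters must be positive")
        d = self.recontact_delay
        if d.p_week < 0.5:
            raise ValueError("recontact delay must place >=0.5 mass in days 0-7")
        if not np.isclose(self.age_pmf.sum(), 1.0):
            raise ValueError("age_pmf must sum to 1")
        if not np.isclose(self.start_time_pmf.sum(), 1.0):
            raise ValueError("start_time_pmf must sum to 1")


@dataclass
class GroundTruth:
    """Per-chatter latent state used as the oracle in parameter-recovery tests."""

    chat_id: str
    age: int
    gender: str
    start_hour: int
    active_topics: tuple[str, ...]
    true_prob: float
    label: bool
    delay_days: float | None


# ---------------------------------------------------------------------------
# intercept calibration


def _latent_bernoullis(config: SynthConfig) -> list[tuple[float, float, float]]:
    """(probability, effect-if-on, effect-if-off) per independent latent driver."""
    e = config.effect_log_odds
    ages = np.arange(config.age_lo, config.age_lo + len(config.age_pmf))
    p_young = float(config.age_pmf[ages <= config.young_age_max].sum())
    p_night = float(config.start_time_pmf[list(config.night_hours)].sum())
    pr = config.topic_priors
    return [
        (p_young, e.get("young", 0.0), 0.0),
        (config.p_female, e.get("female", 0.0), e.get("male", 0.0)),
        (pr.get("self_harm", 0.0), e.get("self_harm", 0.0), 0.0),
        (pr.get("suicide", 0.0), e.get("suicide", 0.0), 0.0),
        (p_night, e.get("night", 0.0), 0.0),
        (pr.get("work", 0.0), e.get("work", 0.0), 0.0),
        (pr.get("redirection", 0.0), e.get("redirection", 0.0), 0.0),
    ]


def calibrate_intercept(config: SynthConfig) -> float:
    """Logistic intercept beta0 making the marginal recontact probability
    match ``target_prevalence`` under the configured latent distribution.

    The latent drivers are independent Bernoullis, so the expectation of
    the logistic response is computed exactly by enumeration and beta0 is
    found by root-finding on [-10, 10].
    """
    terms = _latent_bernoullis(config)
    combos = []
    for bits in itertools.product((0, 1), repeat=len(terms)):
        w = 1.0
        eta = 0.0
        for b, (p, e_on, e_off) in zip(bits, terms):
            w *= p if b else (1.0 - p)
            eta += e_on if b else e_off
        combos.append((w, eta))
    weights = np.array([w for w, _ in combos])
    etas = np.array([eta for _, eta in combos])

    def gap(b0: float) -> float:
        return float(weights @ (1.0 / (1.0 + np.exp(-(b0 + etas))))) - config.target_prevalence

    try:
        return float(optimize.brentq(gap, -10.0, 10.0, xtol=1e-10))
    except ValueError as err:  # no sign change on the bracket
        raise ValueError(
            "no intercept in [-10, 10] achieves the target prevalence"
        ) from err


# ---------------------------------------------------------------------------
# message-count calibration under the qualification filter


def _truncated_count_means(
    m_ch: float, m_co: float, config: SynthConfig
) -> tuple[float, float, float]:
    """Exact (P(qualify), E[chatter|q], E[counselor|q]) for independent NBs
    truncated to the region {chatter >= 1, counselor >= min_counselor,
    total >= min_total} (the chatter opens the chat, so at least one
    chatter message is required)."""
    ch = config.chatter_msg_dist.nbinom(m_ch)
    co = config.counselor_msg_dist.nbinom(m_co)
    mc, mt = config.min_counselor, config.min_total
    # chatter values 1..mt-mc-1 where the total threshold binds on co
    lo = np.arange(1, max(mt - mc, 1))
    p_lo = ch.pmf(lo)
    thresh = np.maximum(mc, mt - lo)
    sf_co = co.sf(thresh - 1)  # P(co >= thresh)
    k = np.arange(0, mt + 1)
    pmf_co = co.pmf(k)
    # E[co * 1(co >= t)] = m_co - sum_{j<t} j pmf(j)
    cum_j_pmf = np.cumsum(k * pmf_co)
    e_co_ge = np.array([m_co - (cum_j_pmf[t - 1] if t > 0 else 0.0) for t in thresh])
    p_hi = float(ch.sf(lo[-1])) if len(lo) else float(ch.sf(0))
    sf3 = float(co.sf(mc - 1))
    e_co_ge3 = m_co - float(cum_j_pmf[mc - 1])
    p_q = float(p_lo @ sf_co) + p_hi * sf3
    e_ch = float((lo * p_lo) @ sf_co) + (m_ch - float(lo @ p_lo)) * sf3
    e_co = float(p_lo @ e_co_ge) + p_hi * e_co_ge3
    return p_q, e_ch / p_q, e_co / p_q


def _calibrate_count_means(config: SynthConfig) -> tuple[float, float]:
    """Pre-truncation NB means such that, conditional on the first
    consultation qualifying, the chatter/counselor message-count means hit
    the configured targets."""
    t_ch = config.chatter_msg_dist.mean
    t_co = config.counselor_msg_dist.mean
    m_ch, m_co = t_ch, t_co
    for _ in range(200):
        _, e_ch, e_co = _truncated_count_means(m_ch, m_co, config)
        step_ch, step_co = e_ch - t_ch, e_co - t_co
        m_ch, m_co = m_ch - step_ch, m_co - step_co
        if abs(step_ch) < 1e-9 and abs(step_co) < 1e-9:
            break
        m_ch = max(m_ch, 1.0)
        m_co = max(m_co, 1.0)
    return m_ch, m_co


# ---------------------------------------------------------------------------
# corpus generation


def _sample_qualifying_counts(
    rng: np.random.Generator, config: SynthConfig, n: int
) -> tuple[np.ndarray, np.ndarray]:
    m_ch, m_co = _calibrate_count_means(config)
    ch_rv = config.chatter_msg_dist.nbinom(m_ch)
    co_rv = config.counselor_msg_dist.nbinom(m_co)
    def bad_mask(a, b):
        return (a < 1) | (b < config.min_counselor) | (a + b < config.min_total)

    n_ch = ch_rv.rvs(size=n, random_state=rng)
    n_co = co_rv.rvs(size=n, random_state=rng)
    bad = bad_mask(n_ch, n_co)
    while bad.any():
        k = int(bad.sum())
        n_ch[bad] = ch_rv.rvs(size=k, random_state=rng)
        n_co[bad] = co_rv.rvs(size=k, random_state=rng)
        bad = bad_mask(n_ch, n_co)
    return n_ch.astype(np.int64), n_co.astype(np.int64)


def _sample_total_words(
    rng: np.random.Generator, config: SynthConfig, n_total: np.ndarray
) -> np.ndarray:
    rv = config.total_words_dist.nbinom()
    cap = config.total_words_dist.cap or np.inf
    w = rv.rvs(size=len(n_total), random_state=rng)
    bad = (w < n_total) | (w > cap)
    while bad.any():
        w[bad] = rv.rvs(size=int(bad.sum()), random_state=rng)
        bad = (w < n_total) | (w > cap)
    return w.astype(np.int64)


def _zipf_weights(n: int, a: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n + 1) ** a
    return w / w.sum()


def _split_words(rng, words, counts):
    """Distribute `words` tokens over len(counts)=n messages, >=1 each."""
    n = len(counts)
    extra = rng.multinomial(words - n, np.ones(n) / n)
    return extra + 1


def generate_corpus(config: SynthConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Generate a message stream and its ground truth.

    Returns ``(messages, truth)``: messages has one row per message with
    columns ``chat_id, sender, sent_at, text`` (text is a space-joined stem
    sequence); truth has one row per chatter with the latent state, the
    true recontact probability, the sampled label and (for positives) the
    recontact delay in days. Fully deterministic given ``config.seed``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_chatters
    lex = config.topic_lexicons
    beta0 = calibrate_intercept(config)

    # --- latent draws -----------------------------------------------------
    ages = config.age_lo + rng.choice(len(config.age_pmf), size=n, p=config.age_pmf)
    female = rng.random(n) < config.p_female
    hours = rng.choice(24, size=n, p=config.start_time_pmf)
    night = np.isin(hours, config.night_hours)
    pr = config.topic_priors
    t_self_harm = rng.random(n) < pr.get("self_harm", 0.0)
    t_suicide = rng.random(n) < pr.get("suicide", 0.0)
    t_work = rng.random(n) < pr.get("work", 0.0)
    t_redirect = rng.random(n) < pr.get("redirection", 0.0)
    t_time = night | (rng.random(n) < pr.get("time_of_day_base", 0.0))
    t_emotion = rng.random(n) < pr.get("emotion_adjectives", 0.0)
    mention_age = rng.random(n) < config.p_mention_age
    mention_gender = rng.random(n) < config.p_mention_gender

    e = config.effect_log_odds
    eta = (
        beta0
        + np.where(ages <= config.young_age_max, e.get("young", 0.0), 0.0)
        + np.where(female, e.get("female", 0.0), e.get("male", 0.0))
        + t_self_harm * e.get("self_harm", 0.0)
        + t_suicide * e.get("suicide", 0.0)
        + night * e.get("night", 0.0)
        + t_work * e.get("work", 0.0)
        + t_redirect * e.get("redirection", 0.0)
    )
    true_prob = 1.0 / (1.0 + np.exp(-eta))
    label = rng.random(n) < true_prob
    delays = np.full(n, np.nan)
    delays[label] = config.recontact_delay.sample(rng, int(label.sum()))

    # --- counts and word budgets -----------------------------------------
    n_ch, n_co = _sample_qualifying_counts(rng, config, n)
    n_tot = n_ch + n_co
    words = _sample_total_words(rng, config, n_tot)
    frac_ch = n_ch / n_tot
    w_ch = np.clip(rng.binomial(words - n_tot, frac_ch) + n_ch, n_ch, words - n_co)
    w_co = words - w_ch

    # chatter-side topics (redirection is counselor-only)
    chatter_topics = {
        "self_harm": t_self_harm,
        "suicide": t_suicide,
        "work": t_work,
        "time_of_day": t_time,
        "emotion_adjectives": t_emotion,
        "numbers": mention_age,
    }
    mirrored = {
        t: act & (rng.random(n) < config.mirror_prob)
        for t, act in chatter_topics.items()
    }

    # forced topic-token counts per chat (>=1 guarantees presence)
    rate = config.topic_token_rate

    def forced(active: np.ndarray, budget: np.ndarray) -> np.ndarray:
        k = np.where(active, np.maximum(1, rng.poisson(rate * budget)), 0)
        return k.astype(np.int64)

    ch_forced = {t: forced(a, w_ch) for t, a in chatter_topics.items()}
    gender_forced = forced(mention_gender, w_ch // 2)
    co_redirect = forced(t_redirect, w_co)

    # keep at least ~40% background so topic tokens never exceed the budget
    def trim(forced_counts: dict, budget: np.ndarray, extra=None):
        total = sum(forced_counts.values()) + (extra if extra is not None else 0)
        over = total > (budget * 0.6).astype(np.int64)
        if over.any():
            scale = np.where(over, (budget * 0.6) / np.maximum(total, 1), 1.0)
            for t in forced_counts:
                forced_counts[t] = np.maximum(
                    np.minimum(forced_counts[t], 1),
                    (forced_counts[t] * scale).astype(np.int64),
                )
        return forced_counts

    ch_forced = trim(ch_forced, w_ch, gender_forced)

    # --- token pools ------------------------------------------------------
    bg = np.asarray(lex["background"], dtype=object)
    bg_w = _zipf_weights(len(bg), config.background_zipf)

    def topic_tokens(name: str, counts: np.ndarray) -> np.ndarray:
        pool = np.asarray(lex[name], dtype=object)
        return rng.choice(pool, size=int(counts.sum()))

    ch_topic_draws = {t: topic_tokens(t, c) for t, c in ch_forced.items()}
    redirect_draws = topic_tokens("redirection", co_redirect)
    gender_pool = [
        np.asarray(config.male_stems, dtype=object),
        np.asarray(config.female_stems, dtype=object),
    ]
    gender_draws = np.concatenate(
        [
            rng.choice(gender_pool[int(f)], size=int(k)) if k else np.empty(0, object)
            for f, k in zip(female, gender_forced)
        ]
    ) if gender_forced.sum() else np.empty(0, object)

    # age stems override the generic numbers draw: chatters state their age
    age_stems = ages.astype(str)

    # --- chatter topic segments and counselor mirror echoes ---------------
    # mirrored topics are echoed by the counselor as the *distinct* stems
    # the chatter actually used, so a mirrored stem is always visible on
    # both sides of the conversation
    offs = {t: np.concatenate([[0], np.cumsum(c)]) for t, c in ch_forced.items()}

    def chatter_segment(topic: str, i: int) -> np.ndarray:
        seg = ch_topic_draws[topic][offs[topic][i]:offs[topic][i + 1]]
        if topic == "numbers" and len(seg):
            seg = np.full(len(seg), age_stems[i], dtype=object)
        return seg

    co_mirror: list[list[str]] = []
    for i in range(n):
        echo: list[str] = []
        for t in ch_forced:
            if mirrored[t][i]:
                echo.extend(dict.fromkeys(chatter_segment(t, i)))
        co_mirror.append(echo)
    co_mirror_counts = np.array([len(e) for e in co_mirror], dtype=np.int64)

    ch_topic_total = sum(ch_forced.values()) + gender_forced
    # forced tokens may (rarely, for tiny chats) exceed the word budget;
    # the channel then carries slightly more words than drawn
    ch_bg = np.maximum(w_ch - ch_topic_total, 0)
    co_bg = np.maximum(w_co - co_mirror_counts - co_redirect, 0)
    bg_tokens = rng.choice(bg, size=int(ch_bg.sum() + co_bg.sum()), p=bg_w)

    # --- assemble per-chat token lists -----------------------------------
    red_off = np.concatenate([[0], np.cumsum(co_redirect)])
    gen_off = np.concatenate([[0], np.cumsum(gender_forced)])
    bg_off = np.concatenate([[0], np.cumsum(np.concatenate([ch_bg, co_bg]))])

    start_dates = _sample_start_times(rng, config, hours)
    chat_ids = np.array([f"c{i:06d}" for i in range(n)])

    rows_chat_id: list[str] = []
    rows_sender: list[str] = []
    rows_time: list[float] = []  # epoch seconds; vector-converted at the end
    rows_text: list[str] = []

    n_recontact_ch, n_recontact_co = 3, 2
    for i in range(n):
        toks_ch: list[str] = []
        for t in ch_forced:
            toks_ch.extend(chatter_segment(t, i))
        toks_ch.extend(gender_draws[gen_off[i]:gen_off[i + 1]])
        toks_ch.extend(bg_tokens[bg_off[i]:bg_off[i + 1]])
        toks_co: list[str] = list(co_mirror[i])
        toks_co.extend(redirect_draws[red_off[i]:red_off[i + 1]])
        toks_co.extend(bg_tokens[bg_off[n + i]:bg_off[n + i + 1]])
        rng.shuffle(toks_ch)
        rng.shuffle(toks_co)

        per_msg_ch = _split_words(rng, len(toks_ch), np.empty(n_ch[i]))
        per_msg_co = _split_words(rng, len(toks_co), np.empty(n_co[i]))
        roles = np.concatenate(
            [np.zeros(n_ch[i], dtype=int), np.ones(n_co[i], dtype=int)]
        )
        rng.shuffle(roles)
        # keep the very first message from the chatter: they open the chat
        if roles[0] == 1:
            j = int(np.argmax(roles == 0))
            roles[0], roles[j] = roles[j], roles[0]

        gaps = rng.uniform(30.0, 1200.0, n_tot[i])  # 0.5-20 min between messages
        gaps[0] = 0.0
        times = start_dates[i] + np.cumsum(gaps)
        pc = np.concatenate([[0], np.cumsum(per_msg_ch)])
        cc = np.concatenate([[0], np.cumsum(per_msg_co)])
        ich = ico = 0
        cid = chat_ids[i]
        for m, r in enumerate(roles):
            if r == 0:
                text = " ".join(toks_ch[pc[ich]:pc[ich + 1]])
                ich += 1
            else:
                text = " ".join(toks_co[cc[ico]:cc[ico + 1]])
                ico += 1
            rows_chat_id.append(cid)
            rows_sender.append("chatter" if r == 0 else "counselor")
            rows_time.append(times[m])
            rows_text.append(text)

        if label[i]:
            t0 = times[-1] + delays[i] * SECONDS_PER_DAY
            extra = rng.choice(bg, size=n_recontact_ch + n_recontact_co, p=bg_w)
            rroles = [0] * n_recontact_ch + [1] * n_recontact_co
            rgaps = np.concatenate([[0.0], rng.uniform(30.0, 1200.0, len(rroles) - 1)])
            rtimes = t0 + np.cumsum(rgaps)
            for m, r in enumerate(rroles):
                rows_chat_id.append(cid)
                rows_sender.append("chatter" if r == 0 else "counselor")
                rows_time.append(rtimes[m])
                rows_text.append(str(extra[m]))

    messages = pd.DataFrame(
        {
            "chat_id": rows_chat_id,
            "sender": rows_sender,
            "sent_at": pd.to_datetime(np.array(rows_time), unit="s").round("s"),
            "text": rows_text,
        }
    )

    active_topics = [
        tuple(
            t for t, act in chatter_topics.items() if act[i] and t != "numbers"
        ) + (("redirection",) if t_redirect[i] else ())
        for i in range(n)
    ]
    truth = pd.DataFrame(
        {
            "chat_id": chat_ids,
            "age": ages,
            "gender": np.where(female, "female", "male"),
            "start_hour": hours,
            "night": night,
            "active_topics": [",".join(t) for t in active_topics],
            "mirrored_topics": [
                ",".join(t for t in chatter_topics if mirrored[t][i])
                for i in range(n)
            ],
            "true_prob": true_prob,
            "label": label,
            "delay_days": delays,
        }
    )
    if config.p_nonqualifying > 0:
        messages, truth = _append_nonqualifying(rng, config, messages, truth)
    return messages, truth


def _sample_start_times(
    rng: np.random.Generator, config: SynthConfig, hours: np.ndarray
) -> np.ndarray:
    """Epoch seconds of each chat's first message: uniform calendar date,
    configured clock-hour distribution, uniform minute/second."""
    d0 = pd.Timestamp(config.calendar_start).timestamp()
    d1 = pd.Timestamp(config.calendar_end).timestamp()
    n_days = int((d1 - d0) // SECONDS_PER_DAY)
    day = rng.integers(0, n_days, size=len(hours))
    sec = rng.integers(0, 3600, size=len(hours))
    return d0 + day * SECONDS_PER_DAY + hours * 3600.0 + sec


def _append_nonqualifying(rng, config, messages, truth):
    """Emulate contacts that never become a consultation (the excluded
    share): a few chatter messages, fewer counselor messages than the
    qualification threshold."""
    n_extra = int(round(config.p_nonqualifying * config.n_chatters))
    bg = np.asarray(config.topic_lexicons["background"], dtype=object)
    hours = rng.choice(24, size=n_extra, p=config.start_time_pmf)
    starts = _sample_start_times(rng, config, hours)
    recs = []
    for i in range(n_extra):
        cid = f"x{i:06d}"
        n_msg = int(rng.integers(1, 6))
        n_co = int(rng.integers(0, min(config.min_counselor, n_msg)))
        roles = [0] * (n_msg - n_co) + [1] * n_co
        t = starts[i]
        for r in roles:
            t += float(rng.uniform(30.0, 1200.0))
            recs.append(
                (cid, "chatter" if r == 0 else "counselor",
                 pd.Timestamp(t, unit="s").round("s"),
                 " ".join(rng.choice(bg, size=int(rng.integers(2, 9)))))
            )
    extra = pd.DataFrame(recs, columns=["chat_id", "sender", "sent_at", "text"])
    return pd.concat([messages, extra], ignore_index=True), truth
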