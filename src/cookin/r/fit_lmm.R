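# Batch fitter for dyadic Gaussian mixed models with two crossed random
# factors (the two members of each dyad) and, optionally, uncorrelated
# random slopes for every fixed covariate.  Driven by the Python package:
#   Rscript fit_lmm.R data.csv jobs.json out.json
# jobs.json: {response, id_a, id_b, models: [{name, fixed: [cols],
#             random: "slopes"|"intercepts", random_cols: [cols], reml}]}

suppressMessages({
  library(lme4)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
data_csv <- args[[1]]
jobs_json <- args[[2]]
out_json <- args[[3]]

jobs <- fromJSON(jobs_json, simplifyDataFrame = FALSE)
dat <- read.csv(data_csv, stringsAsFactors = FALSE)
ids <- sort(unique(c(dat[[jobs$id_a]], dat[[jobs$id_b]])))
dat$.ida <- factor(dat[[jobs$id_a]], levels = ids)
dat$.idb <- factor(dat[[jobs$id_b]], levels = ids)
resp <- jobs$response

ctrl <- lmerControl(optimizer = "nloptwrap", calc.derivs = FALSE,
                    check.conv.singular = "ignore")

build_formula <- function(m) {
  fixed <- unlist(m$fixed)
  fixed_part <- if (length(fixed) == 0) "1" else paste(c("1", fixed), collapse = " + ")
  rnd_cols <- unlist(m$random_cols)
  if (identical(m$random, "slopes") && length(rnd_cols) > 0) {
    rterm <- paste(c("1", rnd_cols), collapse = " + ")
    rnd_part <- sprintf("(%s || .ida) + (%s || .idb)", rterm, rterm)
  } else {
    rnd_part <- "(1 | .ida) + (1 | .idb)"
  }
  as.formula(paste(resp, "~", fixed_part, "+", rnd_part))
}

fit_one <- function(m, d) {
  form <- build_formula(m)
  msgs <- character(0)
  mod <- withCallingHandlers(
    lmer(form, data = d, REML = isTRUE(m$reml), control = ctrl),
    warning = function(w) { msgs <<- c(msgs, conditionMessage(w)); invokeRestart("muffleWarning") },
    message = function(w) { msgs <<- c(msgs, conditionMessage(w)); invokeRestart("muffleMessage") }
  )
  co <- summary(mod)$coefficients
  vc <- as.data.frame(VarCorr(mod))
  list(
    name = m$name, ok = TRUE,
    loglik = as.numeric(logLik(mod)),
    reml = isTRUE(m$reml),
    n_obs = nrow(d),
    coef_names = rownames(co),
    estimate = unname(co[, "Estimate"]),
    se = unname(co[, "Std. Error"]),
    t = unname(co[, "t value"]),
    vc_group = paste(vc$grp, ifelse(is.na(vc$var1), "", vc$var1), sep = ":"),
    vc_var = vc$vcov,
    sigma2 = sigma(mod)^2,
    singular = isSingular(mod),
    converged = length(mod@optinfo$conv$lme4$messages) == 0,
    messages = msgs
  )
}

if (!is.null(jobs$by_rep)) {
  # replicate mode: fit every model on every subset defined by the rep
  # column and report only the log-likelihoods (for LRT simulations)
  reps <- sort(unique(dat[[jobs$by_rep]]))
  results <- lapply(jobs$models, function(m) {
    ll <- vapply(reps, function(r) {
      d <- dat[dat[[jobs$by_rep]] == r, , drop = FALSE]
      d$.ida <- droplevels(d$.ida)
      d$.idb <- droplevels(d$.idb)
      tryCatch(fit_one(m, d)$loglik, error = function(e) NA_real_)
    }, numeric(1))
    list(name = m$name, ok = TRUE, rep = reps, loglik = ll,
         npar_fixed = length(unlist(m$fixed)) + 1)
  })
} else {
  results <- lapply(jobs$models, function(m) {
    tryCatch(fit_one(m, dat), error = function(e) {
      list(name = m$name, ok = FALSE, error = conditionMessage(e))
    })
  })
}

write(toJSON(results, auto_unbox = TRUE, digits = NA, null = "null"), out_json)
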