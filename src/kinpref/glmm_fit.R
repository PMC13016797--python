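# Batched negative-binomial GLMM worker.
#
# Usage: Rscript glmm_fit.R jobs.json data.csv out.json
#
# jobs.json is a list of fit jobs; data.csv holds all rows with a job_id
# column. For each job: build the fixed-effect term set (optionally all
# 2- and 3-way interactions), fit glmmTMB with family nbinom2 and random
# intercepts, prune non-significant interaction terms stepwise (highest
# Wald p first, respecting marginality), and optionally run per-predictor
# likelihood-ratio tests by refitting without the predictor and every
# interaction containing it. Results are written as JSON.

suppressMessages({
  library(glmmTMB)
  library(jsonlite)
})

args <- commandArgs(trailingOnly = TRUE)
stopifnot(length(args) == 3)
jobs <- fromJSON(args[1], simplifyVector = FALSE)
dat <- read.csv(args[2], stringsAsFactors = FALSE)

term_parts <- function(t) strsplit(t, ":", fixed = TRUE)[[1]]

coef_rows_for_term <- function(coef_names, term) {
  parts <- term_parts(term)
  sapply(coef_names, function(r) {
    rp <- term_parts(r)
    if (length(rp) != length(parts)) return(FALSE)
    all(mapply(function(a, b) startsWith(a, b), rp, parts))
  })
}

out <- list()
for (job in jobs) {
  d <- dat[dat$job_id == job$id, , drop = FALSE]
  for (col in names(job$factor_levels)) {
    d[[col]] <- factor(d[[col]], levels = unlist(job$factor_levels[[col]]))
  }
  fixed <- unlist(job$fixed)
  rand <- paste(sprintf("(1 | %s)", unlist(job$random)), collapse = " + ")
  terms <- fixed
  if (isTRUE(job$interactions) && length(fixed) >= 2) {
    terms <- c(terms, combn(fixed, 2, FUN = function(x) paste(x, collapse = ":")))
    if (length(fixed) >= 3) {
      terms <- c(terms, combn(fixed, 3, FUN = function(x) paste(x, collapse = ":")))
    }
  }

  fit_terms <- function(ts) {
    rhs <- if (length(ts)) paste(c(ts, rand), collapse = " + ") else rand
    f <- as.formula(paste(job$response, "~", rhs))
    suppressWarnings(glmmTMB(f, family = nbinom2, data = d))
  }

  res <- tryCatch({
    m <- fit_terms(terms)
    dropped <- character(0)
    alpha <- if (is.null(job$alpha)) 0.05 else job$alpha
    repeat {
      inter <- terms[grepl(":", terms, fixed = TRUE)]
      if (length(inter) == 0) break
      droppable <- inter[sapply(inter, function(t) {
        parts <- term_parts(t)
        higher <- inter[sapply(inter, function(o) length(term_parts(o)) > length(parts))]
        if (length(higher) == 0) return(TRUE)
        !any(sapply(higher, function(o) all(parts %in% term_parts(o))))
      })]
      if (length(droppable) == 0) break
      co <- summary(m)$coefficients$cond
      pvals <- sapply(droppable, function(t) {
        rows <- coef_rows_for_term(rownames(co), t)
        if (!any(rows)) return(NA_real_)
        max(co[rows, 4])
      })
      if (all(is.na(pvals)) || max(pvals, na.rm = TRUE) < alpha) break
      worst <- droppable[which.max(pvals)]
      terms <- setdiff(terms, worst)
      dropped <- c(dropped, worst)
      m <- fit_terms(terms)
    }

    co <- summary(m)$coefficients$cond
    vc <- as.matrix(vcov(m)$cond)
    lr <- list()
    for (pred in unlist(job$lr_tests)) {
      keep <- terms[!sapply(terms, function(t) pred %in% term_parts(t))]
      m0 <- fit_terms(keep)
      chisq <- as.numeric(2 * (logLik(m) - logLik(m0)))
      df <- attr(logLik(m), "df") - attr(logLik(m0), "df")
      lr[[pred]] <- list(
        chisq = chisq, df = df,
        p = pchisq(max(chisq, 0), df, lower.tail = FALSE)
      )
    }
    conv <- isTRUE(m$fit$convergence == 0) && isTRUE(m$sdr$pdHess)
    list(
      ok = TRUE,
      converged = conv,
      loglik = as.numeric(logLik(m)),
      df_model = attr(logLik(m), "df"),
      nobs = nrow(d),
      dispersion = sigma(m),
      dropped = as.list(dropped),
      terms = as.list(rownames(co)),
      estimate = as.list(unname(co[, 1])),
      se = as.list(unname(co[, 2])),
      z = as.list(unname(co[, 3])),
      p = as.list(unname(co[, 4])),
      vcov = vc,
      vcov_names = as.list(rownames(vc)),
      lr = lr
    )
  }, error = function(e) list(ok = FALSE, error = conditionMessage(e)))

  out[[as.character(job$id)]] <- res
}

writeLines(toJSON(out, auto_unbox = TRUE, digits = NA, null = "null"), args[3])
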