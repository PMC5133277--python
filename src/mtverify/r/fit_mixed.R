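# Mixed-model fitting worker: reads a JSON job description, fits (g)lmer/lm(glm)
# models with uncorrelated random slopes, optionally pruning zero-variance
# slopes on singular fits, and writes a JSON array of results.
#
# Invoked as: Rscript fit_mixed.R <job.json>

suppressMessages({
  library(jsonlite)
  library(lme4)
})

args <- commandArgs(trailingOnly = TRUE)
job <- fromJSON(args[[1]], simplifyVector = TRUE, simplifyDataFrame = FALSE)
dat <- read.csv(job$data, stringsAsFactors = FALSE)

fixed_part <- if (length(job$fixed) > 0) paste(job$fixed, collapse = " + ") else "1"

random_token <- function(group, term) {
  if (term == "1") sprintf("(1 | %s)", group) else sprintf("(0 + %s | %s)", term, group)
}

build_formula <- function(response, fixed_part, rterms) {
  rhs <- fixed_part
  if (length(rterms) > 0) {
    rhs <- paste(c(fixed_part, vapply(rterms, function(r) random_token(r$group, r$term), "")),
                 collapse = " + ")
  }
  as.formula(paste(response, "~", rhs))
}

fit_once <- function(d, rterms) {
  form <- build_formula(job$response, fixed_part, rterms)
  if (length(rterms) == 0) {
    if (job$family == "binomial") {
      fit <- glm(form, data = d, family = binomial())
    } else {
      fit <- lm(form, data = d)
    }
    return(list(fit = fit, mixed = FALSE, messages = character(0)))
  }
  msgs <- character(0)
  if (job$family == "binomial") {
    fit <- withCallingHandlers(
      glmer(form, data = d, family = binomial(),
            control = glmerControl(check.conv.singular = "ignore")),
      warning = function(w) { msgs <<- c(msgs, conditionMessage(w)); invokeRestart("muffleWarning") })
  } else {
    fit <- withCallingHandlers(
      lmer(form, data = d, REML = isTRUE(job$reml),
           control = lmerControl(calc.derivs = FALSE, check.conv.singular = "ignore")),
      warning = function(w) { msgs <<- c(msgs, conditionMessage(w)); invokeRestart("muffleWarning") })
  }
  list(fit = fit, mixed = TRUE, messages = msgs)
}

vcomp_table <- function(fit) {
  v <- as.data.frame(VarCorr(fit))
  v$grp_base <- sub("\\.[0-9]+$", "", v$grp)
  v$term <- ifelse(is.na(v$var1), "1",
                   ifelse(v$var1 == "(Intercept)", "1", v$var1))
  v
}

slope_variances <- function(fit, rterms) {
  v <- vcomp_table(fit)
  vars <- numeric(0)
  idx <- integer(0)
  for (i in seq_along(rterms)) {
    r <- rterms[[i]]
    if (r$term == "1") next
    row <- which(v$grp_base == r$group & v$term == r$term)
    if (length(row) >= 1) {
      vars <- c(vars, v$vcov[row[1]])
      idx <- c(idx, i)
    }
  }
  list(vars = vars, idx = idx)
}

fit_with_pruning <- function(d, rterms) {
  pruned <- character(0)
  repeat {
    res <- fit_once(d, rterms)
    if (!res$mixed) {
      return(c(res, list(rterms = rterms, pruned = pruned, singular = FALSE)))
    }
    sing <- isSingular(res$fit, tol = 1e-4)
    if (!isTRUE(job$prune) || !sing) {
      return(c(res, list(rterms = rterms, pruned = pruned, singular = sing)))
    }
    sl <- slope_variances(res$fit, rterms)
    if (length(sl$idx) == 0) {
      return(c(res, list(rterms = rterms, pruned = pruned, singular = sing)))
    }
    drop_i <- sl$idx[which.min(sl$vars)]
    r <- rterms[[drop_i]]
    pruned <- c(pruned, sprintf("%s|%s", r$term, r$group))
    rterms <- rterms[-drop_i]
  }
}

extract <- function(res) {
  fit <- res$fit
  if (res$mixed) {
    ct <- summary(fit)$coefficients
    stat <- ct[, 3]
    v <- vcomp_table(fit)
    vc <- lapply(seq_len(nrow(v)), function(i) {
      list(group = if (v$grp[i] == "Residual") "Residual" else v$grp_base[i],
           term = v$term[i], variance = v$vcov[i])
    })
    conv_ok <- length(res$messages) == 0
  } else {
    ct <- summary(fit)$coefficients
    stat <- ct[, 3]
    s2 <- if (job$family == "binomial") NA else summary(fit)$sigma^2
    vc <- if (is.na(s2)) list() else list(list(group = "Residual", term = "1", variance = s2))
    conv_ok <- TRUE
  }
  list(
    terms = rownames(ct),
    beta = unname(ct[, 1]),
    se = unname(ct[, 2]),
    stat = unname(stat),
    vcomp = vc,
    converged = conv_ok,
    singular = isTRUE(res$singular),
    pruned = res$pruned,
    messages = res$messages,
    random = vapply(res$rterms, function(r) sprintf("%s|%s", r$term, r$group), "")
  )
}

run_one <- function(d) {
  tryCatch({
    rterms <- job$random
    # drop random terms whose grouping column has < 2 levels in this subset
    if (length(rterms) > 0) {
      keep <- vapply(rterms, function(r) length(unique(d[[r$group]])) >= 2, TRUE)
      rterms <- rterms[keep]
    }
    extract(fit_with_pruning(d, rterms))
  }, error = function(e) list(error = conditionMessage(e)))
}

if (!is.null(job$batch) && nchar(job$batch) > 0) {
  ids <- unique(dat[[job$batch]])
  out <- lapply(ids, function(i) {
    r <- run_one(dat[dat[[job$batch]] == i, , drop = FALSE])
    r$batch_id <- i
    r
  })
} else {
  out <- list(run_one(dat))
}

write(toJSON(out, auto_unbox = TRUE, digits = NA, null = "null"), job$out)
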