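# Independent reference implementations for the statistical cross-check.
# Reads a CSV of test cases (kind, x, y, z as ';'-joined numbers) and
# writes a CSV of reference statistics and p-values computed with base R.
args <- commandArgs(trailingOnly = TRUE)
infile <- args[1]
outfile <- args[2]

d <- read.csv(infile, stringsAsFactors = FALSE, colClasses = "character")
vec <- function(s) as.numeric(strsplit(s, ";")[[1]])
fmt <- function(v) sprintf("%.17g", v)

stat <- character(nrow(d))
p <- character(nrow(d))
q <- character(nrow(d))

for (i in seq_len(nrow(d))) {
  kind <- d$kind[i]
  x <- vec(d$x[i])
  if (kind == "t_welch") {
    r <- t.test(x, vec(d$y[i]))
    stat[i] <- fmt(unname(r$statistic)); p[i] <- fmt(r$p.value)
  } else if (kind == "t_pooled") {
    r <- t.test(x, vec(d$y[i]), var.equal = TRUE)
    stat[i] <- fmt(unname(r$statistic)); p[i] <- fmt(r$p.value)
  } else if (kind == "mwu") {
    r <- wilcox.test(x, vec(d$y[i]), exact = FALSE, correct = TRUE)
    stat[i] <- fmt(unname(r$statistic)); p[i] <- fmt(r$p.value)
  } else if (kind == "ks") {
    r <- ks.test(x, vec(d$y[i]))
    stat[i] <- fmt(unname(r$statistic)); p[i] <- fmt(r$p.value)
  } else if (kind == "anova") {
    y <- vec(d$y[i]); z <- vec(d$z[i])
    g <- factor(rep(c("a", "b", "c"), times = c(length(x), length(y), length(z))))
    r <- summary(aov(c(x, y, z) ~ g))[[1]]
    stat[i] <- fmt(r$`F value`[1]); p[i] <- fmt(r$`Pr(>F)`[1])
  } else if (kind == "bh") {
    q[i] <- paste(fmt(p.adjust(x, method = "BH")), collapse = ";")
  } else {
    stop(paste("unknown kind:", kind))
  }
}

write.csv(data.frame(kind = d$kind, stat = stat, p = p, q = q),
          outfile, row.names = FALSE, quote = TRUE)
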