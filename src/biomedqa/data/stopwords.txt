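a
an
the
this
that
these
those
is
are
was
were
be
been
being
am
do
does
did
have
has
had
can
could
may
might
must
shall
should
will
would
of
in
on
for
with
to
by
from
at
as
into
between
during
after
before
about
through
against
among
under
over
without
within
upon
via
and
or
but
nor
not
no
what
which
who
whom
whose
where
when
why
how
i
you
he
she
it
we
they
me
him
her
us
them
its
their
his
your
my
our
more
most
very
also
such
other
than
then
there
here
so
if
because
while
some
any
each
every
both
all
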